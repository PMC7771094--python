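"""Build the reference PPI and the 12 CoPPI networks.

Merges the study PPI edge list (self-interactions and isolated nodes
removed), then weights each PPI edge by the |PCC| of its endpoint genes'
log2(RPKM+1) expression at every spatiotemporal point, dropping edges
that touch unexpressed genes (RPKM <= 1 in all samples).
"""

import argparse
from pathlib import Path

from coppinet import io
from coppinet.network import build_coppi, merge_ppi


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    ap.add_argument("--out", type=Path, default=Path("results/coppi"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    ppi = merge_ppi(io.read_ppi(args.study / "ppi.tsv"))
    print(f"reference PPI: {ppi.number_of_nodes()} nodes, "
          f"{ppi.number_of_edges()} edges")

    reports = []
    for path in sorted((args.study / "expression").glob("*.tsv")):
        point = path.stem
        coppi = build_coppi(ppi, io.read_expression(path), point)
        io.write_coppi(coppi, args.out / f"{point}.tsv")
        reports.append(coppi.report)
        print(f"  {point}: {coppi.n_nodes} expressed nodes, {coppi.n_edges} edges "
              f"({coppi.report['n_dropped_unexpressed']} dropped unexpressed, "
              f"{coppi.report['n_dropped_zero_variance']} zero-variance)")
    io.write_json(reports, args.out / "build_report.json")


if __name__ == "__main__":
    main()
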