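"""Overlay GWAS gene scores on the modules: Zm, Zn, significant modules.

Converts each disorder's gene p-values to probit scores Gw, computes the
raw module score Zm = sum(Gw)/sqrt(#genes) for every module at every
point, standardizes within each (point, disorder) column to Zn, and
selects modules with Zn > 1.96 — producing the per-point significant
module/gene counts the cross-disorder comparison consumes.
"""

import argparse
from pathlib import Path

import pandas as pd

from coppinet import io
from coppinet.disorder_scoring import (
    normalize_matrix,
    proportion_above,
    score_modules,
    select_significant,
)
from coppinet.gene_scores import gene_score_table
from coppinet.module_search import Module


def load_modules(path: Path) -> list[Module]:
    mods = []
    edges_by_point = {}
    edge_path = path.with_name(path.stem + "_edges.tsv")
    edf = pd.read_csv(edge_path, sep="\t")
    table = pd.read_csv(path, sep="\t")
    for row in table.itertuples(index=False):
        genes = frozenset(row.genes.split(";"))
        sub = edf[edf["geneA"].isin(genes) & edf["geneB"].isin(genes)]
        edges = tuple(sorted(
            (min(a, b), max(a, b), float(w))
            for a, b, w in zip(sub["geneA"], sub["geneB"], sub["PCC"])
        ))
        mods.append(Module(point=row.point, nodes=genes, edges=edges, em=row.Em))
    return mods


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    ap.add_argument("--modules", type=Path, default=Path("results/modules"))
    ap.add_argument("--out", type=Path, default=Path("results/zscores"))
    ap.add_argument("--zn-cut", type=float, default=1.96)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    scores = {
        p.stem: gene_score_table(io.read_gene_p(p), p.stem)
        for p in sorted((args.study / "gwas").glob("*.tsv"))
    }
    print(f"disorders: {', '.join(scores)}")

    long_rows, count_rows, prop_rows = [], [], []
    for path in sorted(args.modules.glob("*.tsv")):
        if path.stem.endswith("_edges"):
            continue
        point = path.stem
        mods = load_modules(path)
        if len(mods) < 2:
            continue
        zm = score_modules(mods, scores)
        zn = normalize_matrix(zm)
        for disorder in zm.columns:
            for mid in zm.index:
                long_rows.append(
                    (point, disorder, mid, zm.at[mid, disorder], zn.at[mid, disorder])
                )
        sel = select_significant(zn, args.zn_cut)
        prop = proportion_above(zm, args.zn_cut)
        for d in sorted(sel):
            count_rows.append((point, d, sel[d]["n_modules"], sel[d]["n_genes"]))
            prop_rows.append((point, d, prop[d]))

    pd.DataFrame(long_rows, columns=["point", "disorder", "module_id", "zm", "zn"]).to_csv(
        args.out / "module_z.tsv", sep="\t", index=False)
    counts = pd.DataFrame(count_rows, columns=["point", "disorder", "n_modules", "n_genes"])
    counts.to_csv(args.out / "significant_counts.tsv", sep="\t", index=False)
    pd.DataFrame(prop_rows, columns=["point", "disorder", "prop_zm_above"]).to_csv(
        args.out / "proportion_above.tsv", sep="\t", index=False)

    pivot = counts.pivot(index="point", columns="disorder", values="n_modules")
    print("significant modules (Zn > %.2f) per point:" % args.zn_cut)
    print(pivot.to_string())


if __name__ == "__main__":
    main()
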