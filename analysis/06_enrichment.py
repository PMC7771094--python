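"""Over-representation analysis of each disorder's significant genes.

Tests every (disorder, point) significant-gene union against the study's
gene-set collection with the hypergeometric upper tail, applying the
family-wide Bonferroni threshold alpha / (terms x disorders x points).
"""

import argparse
from pathlib import Path

import pandas as pd

from coppinet import io
from coppinet.enrichment import GeneSetCollection, bonferroni_threshold, hypergeom_ora
from coppinet.network import merge_ppi


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    ap.add_argument("--zscores", type=Path, default=Path("results/zscores"))
    ap.add_argument("--out", type=Path, default=Path("results/enrichment"))
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    sets, names = io.read_gmt(args.study / "genesets.gmt")
    universe = set(merge_ppi(io.read_ppi(args.study / "ppi.tsv")).nodes)
    collection = GeneSetCollection(sets=sets, names=names, universe=universe)

    long = pd.read_csv(args.zscores / "module_z.tsv", sep="\t")
    points = sorted(long["point"].unique())
    disorders = sorted(long["disorder"].unique())
    threshold = bonferroni_threshold(
        args.alpha, collection.n_terms, len(disorders), len(points))
    print(f"Bonferroni family: {collection.n_terms} terms x {len(disorders)} "
          f"disorders x {len(points)} points -> per-test threshold {threshold:.3g}")

    sig = long[long["zn"] > 1.96]
    n_hits = 0
    all_rows = []
    for (point, disorder), sub in sig.groupby(["point", "disorder"]):
        genes = set()
        for mid in sub["module_id"]:
            genes.update(mid.split(";"))
        genes &= universe
        if not genes:
            continue
        res = hypergeom_ora(genes, collection, threshold=threshold)
        res.insert(0, "disorder", disorder)
        res.insert(0, "point", point)
        all_rows.append(res[res["significant"]])
        n_hits += int(res["significant"].sum())
    if all_rows:
        pd.concat(all_rows).to_csv(
            args.out / "significant_terms.tsv", sep="\t", index=False)
    print(f"{n_hits} (point, disorder, term) enrichments below the "
          f"family-wide threshold")


if __name__ == "__main__":
    main()
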