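"""Compare disorders across spatiotemporal points.

Clusters the five disorders by their Zn profiles at every point (1-Pearson
distance, average linkage) and reports how often the planted shared-risk
pairs SCZ-BIP and ASD-ADHD merge before any third disorder joins; computes
the mean-Zm landscape and its per-region peak stage; tabulates module and
gene overlaps among the significant selections; and merges each disorder's
top-10 modules into a subnetwork to call its hub gene.
"""

import argparse
import importlib.util
import json
from pathlib import Path

import pandas as pd

from coppinet.cross_disorder import (
    all_pairs,
    cluster_disorders,
    mean_z_landscape,
    merge_top_and_hub,
    overlap_analysis,
    pair_first_rates,
    peak_stage,
)
from coppinet.disorder_scoring import select_significant, top_modules

_spec = importlib.util.spec_from_file_location(
    "score_stage", Path(__file__).with_name("04_score_disorders.py"))
_stage = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_stage)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    ap.add_argument("--modules", type=Path, default=Path("results/modules"))
    ap.add_argument("--zscores", type=Path, default=Path("results/zscores"))
    ap.add_argument("--out", type=Path, default=Path("results/compare"))
    ap.add_argument("--top-k", type=int, default=10)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    long = pd.read_csv(args.zscores / "module_z.tsv", sep="\t")
    zm_by_point = {
        p: sub.pivot(index="module_id", columns="disorder", values="zm")
        for p, sub in long.groupby("point")
    }
    zn_by_point = {
        p: sub.pivot(index="module_id", columns="disorder", values="zn")
        for p, sub in long.groupby("point")
    }

    dendros = [cluster_disorders(zn_by_point[p], point=p) for p in sorted(zn_by_point)]
    with open(args.out / "dendrograms.nwk", "w") as fh:
        for d in dendros:
            fh.write(f"{d.point}\t{d.newick()}\n")
    rates = pair_first_rates(dendros, all_pairs(dendros[0].labels))
    rates.to_csv(args.out / "pair_first_rates.tsv", sep="\t", index=False)
    print("pairs clustering together first (fraction of points):")
    print(rates.sort_values("rate", ascending=False).head(4).to_string(index=False))

    landscape = mean_z_landscape(zm_by_point)
    landscape.to_csv(args.out / "mean_zm.tsv", sep="\t", index_label="disorder")
    peaks = peak_stage(landscape)
    peaks.to_csv(args.out / "peak_stage.tsv", sep="\t", index=False)

    overlap_rows = []
    for p in sorted(zn_by_point):
        sel = select_significant(zn_by_point[p])
        for kind, sets in (
            ("module", {d: set(sel[d]["module_ids"]) for d in sel}),
            ("gene", {d: sel[d]["genes"] for d in sel}),
        ):
            table = overlap_analysis(sets)
            for row in table[table["multiplicity"] >= 4].itertuples(index=False):
                overlap_rows.append((p, kind, row.item, row.disorders, row.multiplicity))
    shared = pd.DataFrame(
        overlap_rows, columns=["point", "kind", "item", "disorders", "multiplicity"])
    shared.to_csv(args.out / "overlaps.tsv", sep="\t", index=False)
    print(f"{len(shared)} items shared by >=4 disorders at some point")

    hub_rows = []
    for p in sorted(zn_by_point):
        mods = {m.module_id: m for m in _stage.load_modules(args.modules / f"{p}.tsv")}
        top = top_modules(zn_by_point[p], zm_by_point[p], k=args.top_k)
        for disorder in sorted(top):
            picked = [mods[mid] for mid in top[disorder] if mid in mods]
            if picked:
                sub = merge_top_and_hub(picked, disorder=disorder)
                hub_rows.append((p, disorder, sub.hub))
    hubs = pd.DataFrame(hub_rows, columns=["point", "disorder", "hub_gene"])
    hubs.to_csv(args.out / "hub_genes.tsv", sep="\t", index=False)
    frequent = hubs["hub_gene"].value_counts()
    print("most frequent hub genes:", json.dumps(frequent.head(3).to_dict()))


if __name__ == "__main__":
    main()
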