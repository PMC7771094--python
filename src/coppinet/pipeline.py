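"""End-to-end orchestration of the spatiotemporal network analysis.

Stages communicate only through plain-text files under a run directory, so
any stage can be replayed or tested in isolation:

1. build CoPPI networks (one weighted edge list per spatiotemporal point);
2. dense module search per point;
3. gene scores per disorder (gene-level p pass-through, probit Gw);
4. module Zm/Zn scoring and significant-module selection;
5. cross-disorder comparison (dendrograms, mean-Zm landscape, overlaps,
   merged top-module subnetworks with hub genes);
6. optional over-representation analysis of each disorder's significant
   genes against a GMT collection.

A provenance manifest records the config hash and per-stage row counts;
re-running with an identical config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from coppinet import io
from coppinet.cross_disorder import (
    all_pairs,
    cluster_disorders,
    mean_z_landscape,
    merge_top_and_hub,
    overlap_analysis,
    pair_first_rates,
    peak_stage,
)
from coppinet.disorder_scoring import (
    normalize_matrix,
    proportion_above,
    score_modules,
    select_significant,
    top_modules,
)
from coppinet.enrichment import GeneSetCollection, bonferroni_threshold, hypergeom_ora
from coppinet.gene_scores import gene_score_table
from coppinet.module_search import Module, search_modules
from coppinet.network import build_coppi, merge_ppi
from coppinet.synthetic import SyntheticConfig, generate_study

STAGES = (
    "build_coppi",
    "search_modules",
    "gene_scores",
    "disorder_scoring",
    "cross_disorder",
    "enrichment",
)


@dataclass
class RunConfig:
    """All knobs of one pipeline run.

    ``input_dir`` must follow the layout written by :func:`simulate` /
    :func:`coppinet.io.write_study`: ``ppi.tsv``, ``expression/<point>.tsv``,
    ``samples.tsv``, ``gwas/<disorder>.tsv`` and optionally
    ``genesets.gmt``.
    """

    input_dir: str
    output_dir: str
    rpkm_expr: float = 1.0
    seed_pcc: float = 0.5
    min_nodes: int = 4
    zn_cut: float = 1.96
    top_k: int = 10
    flank_bp: int = 50_000
    alpha: float = 0.05
    transform: str = "log2p1"
    norm_scope: str = "per_point"  # or "global"
    missing_policy: str = "drop"
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.transform not in ("log2p1", "none"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.norm_scope not in ("per_point", "global"):
            raise ValueError(f"unknown norm_scope {self.norm_scope!r}")
        if self.missing_policy not in ("drop", "impute"):
            raise ValueError(f"unknown missing_policy {self.missing_policy!r}")
        if self.min_nodes < 2:
            raise ValueError("min_nodes must be >= 2")
        if self.top_k < 1 or self.flank_bp < 0:
            raise ValueError("top_k must be >= 1 and flank_bp >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunResult:
    """In-memory handles to the main per-stage products of a run."""

    out_dir: Path
    manifest: dict
    modules: dict[str, list[Module]] = field(default_factory=dict)
    zm: dict[str, pd.DataFrame] = field(default_factory=dict)
    zn: dict[str, pd.DataFrame] = field(default_factory=dict)


def simulate(config: SyntheticConfig, directory) -> Path:
    """Generate a synthetic study and write it in the pipeline layout."""
    study = generate_study(config)
    return io.write_study(study, directory)


def _load_inputs(input_dir: Path):
    ppi_edges = io.read_ppi(input_dir / "ppi.tsv")
    metadata = io.read_metadata(input_dir / "samples.tsv")
    expression = {
        p.stem: io.read_expression(p)
        for p in sorted((input_dir / "expression").glob("*.tsv"))
    }
    if not expression:
        raise FileNotFoundError(f"no expression matrices under {input_dir}/expression")
    gwas = {
        p.stem: io.read_gene_p(p) for p in sorted((input_dir / "gwas").glob("*.tsv"))
    }
    if not gwas:
        raise FileNotFoundError(f"no GWAS tables under {input_dir}/gwas")
    return ppi_edges, metadata, expression, gwas


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute all stages in order; any stage failure names the stage."""
    input_dir = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"config_hash": config.digest(), "stages": {}}

    stage = "load_inputs"
    try:
        ppi_edges, metadata, expression, gwas = _load_inputs(input_dir)
        points = sorted(expression)
        disorders = sorted(gwas)

        stage = "build_coppi"
        ppi = merge_ppi(ppi_edges)
        coppis = {}
        reports = []
        (out / "coppi").mkdir(exist_ok=True)
        for point in points:
            coppi = build_coppi(
                ppi, expression[point], point,
                transform=config.transform, expr_threshold=config.rpkm_expr,
            )
            coppis[point] = coppi
            reports.append(coppi.report)
            io.write_coppi(coppi, out / "coppi" / f"{point}.tsv")
        io.write_json(reports, out / "coppi" / "build_report.json")
        manifest["stages"][stage] = {
            "n_points": len(points),
            "n_ppi_nodes": ppi.number_of_nodes(),
            "n_ppi_edges": ppi.number_of_edges(),
        }

        stage = "search_modules"
        modules = {}
        (out / "modules").mkdir(exist_ok=True)
        for point in points:
            mods = search_modules(
                coppis[point], min_weight=config.seed_pcc, min_nodes=config.min_nodes
            )
            modules[point] = mods
            io.write_modules(mods, out / "modules" / f"{point}.tsv")
            io.write_module_edges(mods, out / "modules" / f"{point}_edges.tsv")
        manifest["stages"][stage] = {p: len(modules[p]) for p in points}

        stage = "gene_scores"
        scores = {}
        (out / "scores").mkdir(exist_ok=True)
        for disorder in disorders:
            scores[disorder] = gene_score_table(gwas[disorder], disorder)
            io.write_gene_p(scores[disorder], out / "scores" / f"{disorder}.tsv")
        manifest["stages"][stage] = {d: len(scores[d]) for d in disorders}

        stage = "disorder_scoring"
        zm_by_point, zn_by_point = {}, {}
        skipped_points = []
        (out / "zscores").mkdir(exist_ok=True)
        for point in points:
            # a Zn column needs >=2 modules to be standardizable
            if len(modules[point]) < 2:
                skipped_points.append(point)
                continue
            zm = score_modules(modules[point], scores, config.missing_policy)
            zm_by_point[point] = zm
        if config.norm_scope == "per_point":
            for point, zm in zm_by_point.items():
                zn_by_point[point] = normalize_matrix(zm)
        else:  # global: one normalization family per disorder across all points
            stacked = pd.concat(
                [zm.assign(_point=p) for p, zm in zm_by_point.items()]
            )
            norm = normalize_matrix(stacked.drop(columns="_point"))
            norm["_point"] = stacked["_point"].to_numpy()
            for point in zm_by_point:
                zn_by_point[point] = norm[norm["_point"] == point].drop(
                    columns="_point"
                )
        long_rows = []
        for point in zm_by_point:
            zm, zn = zm_by_point[point], zn_by_point[point]
            for disorder in zm.columns:
                for mid in zm.index:
                    long_rows.append(
                        (point, disorder, mid, zm.at[mid, disorder], zn.at[mid, disorder])
                    )
        pd.DataFrame(
            long_rows, columns=["point", "disorder", "module_id", "zm", "zn"]
        ).to_csv(out / "zscores" / "module_z.tsv", sep="\t", index=False)

        selected = {
            point: select_significant(zn_by_point[point], config.zn_cut)
            for point in zn_by_point
        }
        summary_rows = [
            (point, d, sel[d]["n_modules"], sel[d]["n_genes"])
            for point, sel in selected.items()
            for d in sorted(sel)
        ]
        pd.DataFrame(
            summary_rows, columns=["point", "disorder", "n_modules", "n_genes"]
        ).to_csv(out / "zscores" / "significant_counts.tsv", sep="\t", index=False)
        prop_rows = []
        for point in zm_by_point:
            prop = proportion_above(zm_by_point[point], config.zn_cut)
            prop_rows += [(point, d, prop[d]) for d in prop.index]
        pd.DataFrame(prop_rows, columns=["point", "disorder", "prop_zm_above"]).to_csv(
            out / "zscores" / "proportion_above.tsv", sep="\t", index=False
        )
        with open(out / "zscores" / "significant_genes.tsv", "w") as fh:
            fh.write("point\tdisorder\tgenes\n")
            for point in sorted(selected):
                for d in sorted(selected[point]):
                    fh.write(
                        f"{point}\t{d}\t{';'.join(sorted(selected[point][d]['genes']))}\n"
                    )
        manifest["stages"][stage] = {
            "n_scored_points": len(zm_by_point),
            "skipped_points": skipped_points,
            "n_significant_total": int(sum(r[2] for r in summary_rows)),
        }

        stage = "cross_disorder"
        (out / "compare").mkdir(exist_ok=True)
        dendros = []
        for point in sorted(zn_by_point):
            if zn_by_point[point].shape[0] >= 2:
                dendros.append(cluster_disorders(zn_by_point[point], point=point))
        with open(out / "compare" / "dendrograms.nwk", "w") as fh:
            for d in dendros:
                fh.write(f"{d.point}\t{d.newick()}\n")
        if dendros:
            pair_first_rates(dendros, all_pairs(dendros[0].labels)).to_csv(
                out / "compare" / "pair_first_rates.tsv", sep="\t", index=False
            )
        landscape = mean_z_landscape(zm_by_point)
        landscape.to_csv(out / "compare" / "mean_zm.tsv", sep="\t", index_label="disorder")
        peak_stage(landscape).to_csv(
            out / "compare" / "peak_stage.tsv", sep="\t", index=False
        )
        overlap_rows = []
        for point in sorted(selected):
            mod_sets = {d: set(selected[point][d]["module_ids"]) for d in selected[point]}
            gene_sets = {d: selected[point][d]["genes"] for d in selected[point]}
            for kind, sets in (("module", mod_sets), ("gene", gene_sets)):
                table = overlap_analysis(sets)
                table = table[table["multiplicity"] >= 2]
                for row in table.itertuples(index=False):
                    overlap_rows.append((point, kind, row.item, row.disorders,
                                         row.multiplicity))
        pd.DataFrame(
            overlap_rows, columns=["point", "kind", "item", "disorders", "multiplicity"]
        ).to_csv(out / "compare" / "overlaps.tsv", sep="\t", index=False)

        hub_rows = []
        (out / "compare" / "subnetworks").mkdir(exist_ok=True)
        for point in sorted(zn_by_point):
            top = top_modules(zn_by_point[point], zm_by_point[point], k=config.top_k)
            by_id = {m.module_id: m for m in modules[point]}
            for disorder in sorted(top):
                mods = [by_id[mid] for mid in top[disorder]]
                if not mods:
                    continue
                gwas_p = pd.Series(
                    scores[disorder]["p"].to_numpy(), index=scores[disorder]["gene"]
                )
                sub = merge_top_and_hub(mods, disorder=disorder, gwas_p=gwas_p)
                sub.node_table.to_csv(
                    out / "compare" / "subnetworks" / f"{disorder}_{point}_nodes.tsv",
                    sep="\t", index=False,
                )
                hub_rows.append((point, disorder, sub.hub))
        pd.DataFrame(hub_rows, columns=["point", "disorder", "hub_gene"]).to_csv(
            out / "compare" / "hub_genes.tsv", sep="\t", index=False
        )
        manifest["stages"][stage] = {
            "n_dendrograms": len(dendros),
            "n_hub_assignments": len(hub_rows),
        }

        stage = "enrichment"
        gmt_path = input_dir / "genesets.gmt"
        if gmt_path.exists():
            sets, names = io.read_gmt(gmt_path)
            universe = set(ppi.nodes)
            collection = GeneSetCollection(sets=sets, names=names, universe=universe)
            threshold = bonferroni_threshold(
                config.alpha, collection.n_terms, len(disorders), len(points)
            )
            (out / "enrichment").mkdir(exist_ok=True)
            n_tests = 0
            for point in sorted(selected):
                for disorder in sorted(selected[point]):
                    query = selected[point][disorder]["genes"] & universe
                    if not query:
                        continue
                    res = hypergeom_ora(query, collection, threshold=threshold)
                    res.to_csv(
                        out / "enrichment" / f"{disorder}_{point}.tsv",
                        sep="\t", index=False,
                    )
                    n_tests += len(res)
            manifest["stages"][stage] = {
                "bonferroni_threshold": threshold, "n_tests": n_tests,
            }
        else:
            manifest["stages"][stage] = {"skipped": "no genesets.gmt in input"}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    from coppinet import __version__

    manifest["version"] = __version__
    io.write_json(manifest, out / "manifest.json")
    return RunResult(
        out_dir=out, manifest=manifest, modules=modules, zm=zm_by_point, zn=zn_by_point
    )
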