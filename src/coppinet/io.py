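"""Plain-text readers and writers for the pipeline's file formats.

Everything on disk is TSV, BED, GMT or JSON so any stage can be replayed
and inspected by hand.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from coppinet.module_search import Module
from coppinet.network import CoppiNetwork
from coppinet.synthetic import SyntheticStudy


# --- edge lists ---------------------------------------------------------

def write_ppi(edges: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for u, v in edges:
            fh.write(f"{u}\t{v}\n")


def read_ppi(path) -> list[tuple[str, str]]:
    edges = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0]:
                edges.append((parts[0], parts[1]))
    return edges


def write_coppi(coppi: CoppiNetwork, path) -> None:
    """Weighted edge list: geneA, geneB, weight, point."""
    rows = sorted(
        (min(u, v), max(u, v), d["weight"]) for u, v, d in coppi.graph.edges(data=True)
    )
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\tweight\tpoint\n")
        for u, v, w in rows:
            fh.write(f"{u}\t{v}\t{w:.10g}\t{coppi.point}\n")


# --- expression ---------------------------------------------------------

def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


# --- GWAS / gene scores -------------------------------------------------

def write_gene_p(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gene_p(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(bed: pd.DataFrame, path) -> None:
    bed[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "gene"]
    )


# --- modules ------------------------------------------------------------

def write_modules(modules: Iterable[Module], path) -> None:
    with open(path, "w") as fh:
        fh.write("module_id\tpoint\tn_nodes\tn_edges\tEm\tgenes\n")
        for m in modules:
            fh.write(
                f"{m.module_id}\t{m.point}\t{m.n_nodes}\t{m.n_edges}"
                f"\t{m.em:.10g}\t{';'.join(sorted(m.nodes))}\n"
            )


def write_module_edges(modules: Iterable[Module], path) -> None:
    """Per-module edge weights: geneA, geneB, PCC, point."""
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\tPCC\tpoint\n")
        for m in modules:
            for u, v, w in m.edges:
                fh.write(f"{u}\t{v}\t{w:.10g}\t{m.point}\n")


# --- gene sets ----------------------------------------------------------

def read_gmt(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """GMT: term id, description, then member genes, tab-separated."""
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
            names[parts[0]] = parts[1]
    return sets, names


def write_gmt(sets: Mapping[str, Iterable[str]], path,
              names: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for term in sorted(sets):
            desc = names.get(term, term) if names else term
            fh.write("\t".join([term, desc, *sorted(sets[term])]) + "\n")


# --- JSON ---------------------------------------------------------------

def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


# --- synthetic study on disk -------------------------------------------

def write_study(study: SyntheticStudy, directory) -> Path:
    """Materialize a synthetic study in the pipeline's input layout."""
    root = Path(directory)
    (root / "expression").mkdir(parents=True, exist_ok=True)
    (root / "gwas").mkdir(exist_ok=True)
    write_ppi(study.ppi, root / "ppi.tsv")
    for point, expr in study.expression.items():
        write_expression(expr, root / "expression" / f"{point}.tsv")
    write_metadata(study.sample_metadata, root / "samples.tsv")
    for disorder, table in study.gwas.items():
        write_gene_p(table, root / "gwas" / f"{disorder}.tsv")
    write_json(study.truth, root / "truth.json")
    return root
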