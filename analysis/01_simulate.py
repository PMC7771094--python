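"""Generate the synthetic study: expression, PPI, GWAS tables, ground truth.

Writes the study under results/study/ in the layout every later stage
reads: ppi.tsv, expression/<point>.tsv, samples.tsv, gwas/<disorder>.tsv,
genesets.gmt and truth.json.
"""

import argparse
from pathlib import Path

from coppinet import io
from coppinet.synthetic import default_config, generate_gene_sets, generate_study


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    config = default_config(rng_seed=args.seed)
    study = generate_study(config)
    root = io.write_study(study, args.out)
    io.write_gmt(generate_gene_sets(config), root / "genesets.gmt")

    n_risk = {d: len(g) for d, g in study.truth["risk_genes"].items()}
    print(f"study written to {root}")
    print(f"  {len(study.expression)} spatiotemporal points, "
          f"{config.n_samples_per_point} samples each")
    print(f"  PPI: {len(study.ppi)} edges over {config.n_genes} genes")
    print(f"  planted modules: {len(config.planted_modules)} "
          f"(5 genes, rho {config.planted_modules[0].rho})")
    print(f"  risk genes per disorder: {n_risk}")


if __name__ == "__main__":
    main()
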