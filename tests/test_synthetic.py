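import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coppinet.synthetic import (
    PlantedModule,
    SyntheticConfig,
    assign_risk_genes,
    default_config,
    generate_expression,
    generate_gwas,
    generate_ppi,
    generate_snp_level,
    generate_study,
)


def bfs_connected(edges, members):
    """Independent connectivity check by breadth-first traversal."""
    members = set(members)
    adj: dict = {m: set() for m in members}
    for u, v in edges:
        if u in members and v in members:
            adj[u].add(v)
            adj[v].add(u)
    start = next(iter(members))
    seen, frontier = {start}, [start]
    while frontier:
        nxt = []
        for node in frontier:
            for nb in adj[node] - seen:
                seen.add(nb)
                nxt.append(nb)
        frontier = nxt
    return seen == members


def small_config(**overrides):
    params = dict(
        n_genes=40,
        n_ppi_edges=120,
        n_samples_per_point=10,
        planted_modules=(
            PlantedModule(("G0000", "G0001", "G0002", "G0003", "G0004"),
                          ("FC_ST1", "SM_ST2"), 0.9),
        ),
        risk_genes_per_disorder=6,
        shared_risk_pairs=(("SCZ", "BIP", 3),),
        rng_seed=1,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


class TestConfigValidation:
    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            small_config(planted_modules=(
                PlantedModule(("G0000", "G0001", "G0002", "G0003"), ("FC_ST1",), 1.5),
            ))

    def test_too_small_module_rejected(self):
        with pytest.raises(ValueError, match=">=4 genes"):
            small_config(planted_modules=(
                PlantedModule(("G0000", "G0001", "G0002"), ("FC_ST1",), 0.9),
            ))

    def test_unknown_active_point_rejected(self):
        with pytest.raises(ValueError, match="unknown point"):
            small_config(planted_modules=(
                PlantedModule(("G0000", "G0001", "G0002", "G0003"), ("XX_ST9",), 0.9),
            ))

    def test_shared_count_exceeding_risk_budget_rejected(self):
        with pytest.raises(ValueError, match="exceeds risk_genes_per_disorder"):
            small_config(shared_risk_pairs=(("SCZ", "BIP", 10),))

    def test_infeasible_edge_count_rejected(self):
        with pytest.raises(ValueError, match="possible pairs"):
            small_config(n_genes=5, n_ppi_edges=11)


class TestGeneratePpi:
    def test_saturated_budget_gives_complete_graph(self):
        cfg = small_config(n_genes=10, n_ppi_edges=45, planted_modules=(),
                           risk_genes_per_disorder=2, shared_risk_pairs=())
        edges = generate_ppi(cfg)
        assert len(edges) == 45
        assert len({frozenset(e) for e in edges}) == 45

    def test_simple_graph_no_self_loops(self):
        edges = generate_ppi(small_config())
        assert all(u != v for u, v in edges)
        assert len({frozenset(e) for e in edges}) == len(edges)

    def test_planted_module_genes_connected(self):
        cfg = small_config()
        edges = generate_ppi(cfg)
        assert bfs_connected(edges, cfg.planted_modules[0].genes)


class TestGenerateExpression:
    def test_high_rho_module_strongly_coexpressed(self):
        cfg = small_config(
            n_samples_per_point=50,
            planted_modules=(
                PlantedModule(("G0000", "G0001", "G0002", "G0003", "G0004"),
                              ("FC_ST1",), 0.99),
            ),
        )
        expr, _ = generate_expression(cfg, points=["FC_ST1"])
        x = np.log2(expr["FC_ST1"].loc[list(cfg.planted_modules[0].genes)] + 1)
        corr = np.corrcoef(x)
        off = np.abs(corr[np.triu_indices(5, 1)])
        assert off.mean() > 0.9

    def test_inactive_point_indistinguishable_from_background(self, rng):
        cfg = small_config(n_samples_per_point=20)
        expr, _ = generate_expression(cfg, points=["FC_ST2"])  # module not active
        x = np.log2(expr["FC_ST2"].to_numpy() + 1)
        module_idx = [0, 1, 2, 3, 4]
        corr = np.abs(np.corrcoef(x))
        mod_mean = corr[np.ix_(module_idx, module_idx)][np.triu_indices(5, 1)].mean()
        # permutation reference: mean |PCC| of random 5-gene sets
        null = []
        for _ in range(200):
            pick = rng.choice(cfg.n_genes, 5, replace=False)
            null.append(corr[np.ix_(pick, pick)][np.triu_indices(5, 1)].mean())
        assert abs(mod_mean - np.mean(null)) < 4 * np.std(null)

    def test_silenced_fraction_below_rpkm_one(self):
        cfg = small_config(silenced_fraction=0.1, planted_modules=())
        expr, _ = generate_expression(cfg, points=["FC_ST1"])
        frac = (expr["FC_ST1"].max(axis=1) < 1.0).mean()
        assert frac == pytest.approx(0.1, abs=0.03)

    def test_values_non_negative(self):
        expr, meta = generate_expression(small_config())
        for mat in expr.values():
            assert (mat.to_numpy() >= 0).all()
        assert set(meta.columns) == {"sample", "region", "stage"}

    def test_unknown_point_label_rejected(self):
        with pytest.raises(ValueError, match="XX_ST9"):
            generate_expression(small_config(), points=["XX_ST9"])

    def test_coexpression_monotone_in_rho(self):
        means = []
        for rho in (0.3, 0.6, 0.9):
            cfg = small_config(
                n_samples_per_point=60,
                planted_modules=(
                    PlantedModule(("G0000", "G0001", "G0002", "G0003", "G0004"),
                                  ("FC_ST1",), rho),
                ),
            )
            expr, _ = generate_expression(cfg, points=["FC_ST1"])
            x = np.log2(expr["FC_ST1"].iloc[:5] + 1)
            corr = np.abs(np.corrcoef(x))
            means.append(corr[np.triu_indices(5, 1)].mean())
        assert means[0] < means[1] < means[2]


class TestGenerateGwas:
    def test_risk_p_stochastically_smaller(self):
        cfg = small_config(n_genes=200, n_ppi_edges=400,
                           risk_genes_per_disorder=50,
                           shared_risk_pairs=(), planted_modules=())
        gwas, risk = generate_gwas(cfg)
        t = gwas["SCZ"].set_index("gene")
        risk_med = t.loc[sorted(risk["SCZ"]), "p"].median()
        null_med = t.drop(index=sorted(risk["SCZ"]))["p"].median()
        assert risk_med < null_med

    def test_shared_pair_overlap_at_least_requested(self):
        cfg = small_config()
        _, risk = generate_gwas(cfg)
        assert len(risk["SCZ"] & risk["BIP"]) >= 3

    def test_p_values_in_unit_interval(self):
        gwas, _ = generate_gwas(small_config())
        for table in gwas.values():
            assert ((table["p"] > 0) & (table["p"] <= 1)).all()

    def test_null_p_uniform(self):
        cfg = small_config(n_genes=1500, n_ppi_edges=2000,
                           risk_genes_per_disorder=10,
                           shared_risk_pairs=(), planted_modules=())
        gwas, risk = generate_gwas(cfg)
        t = gwas["MDD"].set_index("gene")
        null_p = t.drop(index=sorted(risk["MDD"]))["p"]
        assert stats.kstest(null_p, "uniform").pvalue > 0.01

    def test_modular_architecture_uses_whole_modules(self):
        cfg = default_config(rng_seed=3)
        risk = assign_risk_genes(cfg)
        shared = risk["SCZ"] & risk["BIP"]
        full = sum(
            set(pm.genes) <= shared for pm in cfg.planted_modules
        )
        assert full >= 4  # most of the 25 shared genes arrive as whole modules


class TestGenerateSnpLevel:
    def test_positions_within_gene_flanks(self):
        table = pd.DataFrame({"gene": ["G0", "G1"], "p": [0.5, 0.5]})
        snps, ld, bed = generate_snp_level(table, snps_per_gene=5, ld_rho=0.3,
                                           rng_seed=1)
        bed_idx = bed.set_index("gene")
        for gene, sub in snps.groupby(snps["snp"].str.split("_").str[0]):
            start, end = bed_idx.at[gene, "start"], bed_idx.at[gene, "end"]
            pos0 = sub["bp"] - 1
            assert ((start - 50_000 < pos0) & (pos0 < end + 50_000)).all()

    def test_null_single_snp_p_uniform(self):
        table = pd.DataFrame({"gene": [f"G{i}" for i in range(1500)], "p": 0.5})
        snps, _, _ = generate_snp_level(table, snps_per_gene=1, ld_rho=0.0,
                                        rng_seed=2)
        assert stats.kstest(snps["p"], "uniform").pvalue > 0.01

    def test_risk_shift_lowers_p(self):
        table = pd.DataFrame({"gene": [f"G{i}" for i in range(200)], "p": 0.5})
        snps, _, _ = generate_snp_level(
            table, snps_per_gene=3, ld_rho=0.2, rng_seed=3,
            risk_genes={f"G{i}" for i in range(100)}, risk_shift=3.0,
        )
        gene = snps["snp"].str.split("_").str[0]
        idx = gene.str.slice(1).astype(int)
        assert snps.loc[idx < 100, "p"].median() < snps.loc[idx >= 100, "p"].median()

    def test_invalid_parameters_rejected(self):
        table = pd.DataFrame({"gene": ["G0"], "p": [0.5]})
        with pytest.raises(ValueError, match="snps_per_gene"):
            generate_snp_level(table, 0, 0.2, 1)
        with pytest.raises(ValueError, match="ld_rho"):
            generate_snp_level(table, 2, 1.0, 1)


class TestDeterminism:
    def test_same_seed_reproduces_bit_identical_tables(self):
        a, b = generate_study(small_config()), generate_study(small_config())
        assert a.ppi == b.ppi
        for point in a.expression:
            pd.testing.assert_frame_equal(a.expression[point], b.expression[point])
        for d in a.gwas:
            pd.testing.assert_frame_equal(a.gwas[d], b.gwas[d])
        assert a.truth == b.truth

    def test_adding_a_disorder_leaves_expression_unchanged(self):
        a = generate_study(small_config())
        b = generate_study(
            small_config(disorders=("ADHD", "ASD", "BIP", "MDD", "SCZ", "XDD"))
        )
        for point in a.expression:
            pd.testing.assert_frame_equal(a.expression[point], b.expression[point])

    def test_study_invariants(self):
        study = generate_study(small_config())
        pm = study.config.planted_modules[0]
        ppi_pairs = {frozenset(e) for e in study.ppi}
        for g in pm.genes:
            assert any(
                frozenset((g, other)) in ppi_pairs for other in pm.genes if other != g
            )
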