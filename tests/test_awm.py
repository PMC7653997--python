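"""AWM construction, gene assignment and per-gene SNP selection,
including an exhaustive rule-by-rule oracle on small instances."""

import numpy as np
import pandas as pd
import pytest

from feednet import (
    AWMConfig,
    ValidationError,
    assign_genes,
    build_awm,
    select_snp_per_gene,
    summarize_network,
)

# ----------------------------------------------------- brute-force oracle


def awm_oracle(results, cfg):
    """Plain-python re-statement of the selection rules: key SNPs at
    P <= p_threshold, trait retention at |pearson r| >= r_threshold over
    key SNPs, secondary SNPs hitting >= min_other_traits retained
    non-key traits."""
    key = cfg.key_trait
    traits = list(results)
    ids = results[key]["variant_id"].tolist()
    p = {t: dict(zip(results[t]["variant_id"], results[t]["p"])) for t in traits}
    z = {t: dict(zip(results[t]["variant_id"], results[t]["z"])) for t in traits}

    stage1 = [v for v in ids if p[key][v] <= cfg.p_threshold]

    def pearson(xs, ys):
        n = len(xs)
        if n < 2:
            return float("nan")
        mx, my = sum(xs) / n, sum(ys) / n
        sxx = sum((x - mx) ** 2 for x in xs)
        syy = sum((y - my) ** 2 for y in ys)
        sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
        if sxx == 0 or syy == 0:
            return float("nan")
        return sxy / (sxx * syy) ** 0.5

    retained = [key]
    for t in traits:
        if t == key:
            continue
        r = pearson([z[key][v] for v in stage1], [z[t][v] for v in stage1])
        if r == r and abs(r) >= cfg.r_threshold:
            retained.append(t)

    secondary = []
    for v in ids:
        if v in stage1:
            continue
        hits = sum(
            1 for t in retained if t != key and p[t][v] <= cfg.p_threshold
        )
        if hits >= cfg.min_other_traits:
            secondary.append(v)
    rows = [v for v in ids if v in set(stage1) | set(secondary)]
    return rows, retained, set(stage1)


def gene_selection_oracle(rows, retained, results, cfg, gene_of, meta):
    """Per gene: max trait count, then min summed P over associated
    traits, then genomic position."""
    key = cfg.key_trait
    p = {t: dict(zip(results[t]["variant_id"], results[t]["p"])) for t in results}
    by_gene = {}
    for v in rows:
        gene = gene_of.get(v)
        if gene is None:
            continue
        traits = [t for t in retained if p[t][v] <= cfg.p_threshold]
        cum = sum(p[t][v] for t in traits)
        chrom, pos = meta[v]
        by_gene.setdefault(gene, []).append(
            (-len(traits), cum, float(chrom), pos, v, traits)
        )
    out = {}
    for gene, cands in by_gene.items():
        cands.sort()
        best = cands[0]
        out[gene] = (best[4], -best[0], tuple(best[5]), best[1])
    return out


def random_instance(seed, n_var=12, n_traits=6):
    rng = np.random.default_rng(seed)
    ids = [f"v{i}" for i in range(n_var)]
    meta = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": rng.integers(1, 4, n_var).astype(str),
            "pos": rng.choice(np.arange(100, 10000), n_var, replace=False),
        }
    )
    traits = [f"T{k}" for k in range(n_traits)]
    results = {}
    zs = rng.standard_normal((n_var, n_traits)) * 2.5
    for k, t in enumerate(traits):
        df = meta.copy()
        df["z"] = zs[:, k]
        # sprinkle sub-threshold p-values to exercise every rule
        pvals = rng.uniform(0, 1, n_var)
        low = rng.uniform(size=n_var) < 0.35
        pvals[low] = rng.uniform(0, 0.002, low.sum())
        df["p"] = pvals
        results[t] = df
    return results, meta


class TestBuildAWM:
    def test_three_stage_rules_on_toy_instance(self, toy_gwas_results):
        cfg = AWMConfig(key_trait="KEY")
        awm = build_awm(toy_gwas_results, cfg)
        assert sorted(awm.z.index) == ["v1", "v2"]
        assert awm.retained_traits == ["KEY", "B"]
        assert (awm.origin == "key").all()

    def test_all_null_gives_empty_matrix(self, toy_gwas_results):
        flat = {
            t: df.assign(p=0.5) for t, df in toy_gwas_results.items()
        }
        with pytest.warns(UserWarning):
            awm = build_awm(flat, AWMConfig(key_trait="KEY"))
        assert awm.is_empty()
        assert awm.retained_traits == ["KEY"]

    def test_threshold_boundary_inclusive(self, toy_gwas_results):
        res = {t: df.copy() for t, df in toy_gwas_results.items()}
        res["KEY"].loc[res["KEY"]["variant_id"] == "v3", "p"] = 0.001
        awm = build_awm(res, AWMConfig(key_trait="KEY"))
        assert "v3" in awm.z.index

    def test_missing_key_trait_rejected(self, toy_gwas_results):
        with pytest.raises(ValidationError):
            build_awm(toy_gwas_results, AWMConfig(key_trait="NOPE"))

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_oracle(self, seed):
        results, meta = random_instance(seed)
        cfg = AWMConfig(key_trait="T0")
        rows, retained, stage1 = awm_oracle(results, cfg)
        awm = build_awm(results, cfg)
        assert awm.z.index.tolist() == rows
        assert awm.retained_traits == retained
        assert set(awm.origin.index[awm.origin == "key"]) == stage1

    def test_p_threshold_monotonicity(self):
        results, _ = random_instance(99)
        tight = build_awm(results, AWMConfig(key_trait="T0", p_threshold=0.001))
        loose = build_awm(results, AWMConfig(key_trait="T0", p_threshold=0.05))
        tight_keys = set(tight.origin.index[tight.origin == "key"])
        loose_keys = set(loose.origin.index[loose.origin == "key"])
        assert tight_keys <= loose_keys

    def test_r_threshold_monotonicity(self):
        results, _ = random_instance(7)
        strict = build_awm(results, AWMConfig(key_trait="T0", r_threshold=0.8))
        relaxed = build_awm(results, AWMConfig(key_trait="T0", r_threshold=0.1))
        assert set(strict.retained_traits) <= set(relaxed.retained_traits)


class TestAssignGenes:
    @pytest.fixture()
    def ann(self):
        return pd.DataFrame(
            {
                "gene_id": ["g1", "g2"],
                "chrom": ["1", "1"],
                "start": [100, 140],
                "end": [200, 400],
                "strand": ["+", "+"],
            }
        )

    def _variants(self, positions):
        return pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(len(positions))],
                "chrom": "1",
                "pos": positions,
            }
        )

    def test_within_gene_assigned(self, ann):
        out = assign_genes(self._variants([150]), ann.iloc[:1])
        assert out["v0"] == "g1"

    def test_intergenic_unassigned(self, ann):
        out = assign_genes(self._variants([250]), ann.iloc[:1])
        assert "v0" not in out.index

    def test_overlap_resolved_by_nearest_midpoint(self, ann):
        # g1 mid 150, g2 mid 270: variant at 150 goes to g1
        out = assign_genes(self._variants([150]), ann)
        assert out["v0"] == "g1"
        out2 = assign_genes(self._variants([260]), ann)
        assert out2["v0"] == "g2"

    def test_boundary_positions_inclusive(self, ann):
        out = assign_genes(self._variants([100, 200]), ann.iloc[:1])
        assert out["v0"] == "g1" and out["v1"] == "g1"

    def test_chromosome_label_mismatch_rejected(self, ann):
        chr_style = ann.assign(chrom=["chr1", "chr1"])
        with pytest.raises(ValidationError, match="chromosome"):
            assign_genes(self._variants([150]), chr_style)


class TestSelectSnpPerGene:
    def _awm_from(self, results, key="T0"):
        return build_awm(results, AWMConfig(key_trait=key))

    def test_most_traits_wins(self, toy_gwas_results):
        res = {t: df.copy() for t, df in toy_gwas_results.items()}
        # v1 associated with KEY+B (p<=0.001 for both), v2 with KEY only
        res["B"].loc[res["B"]["variant_id"] == "v1", "p"] = 0.0005
        awm = build_awm(res, AWMConfig(key_trait="KEY"))
        gene_map = pd.Series({"v1": "G", "v2": "G"})
        table, _ = select_snp_per_gene(awm, gene_map)
        assert table.loc[0, "variant_id"] == "v1"
        assert table.loc[0, "n_traits_associated"] == 2

    def test_tie_broken_by_cumulated_p(self, toy_gwas_results):
        res = {t: df.copy() for t, df in toy_gwas_results.items()}
        awm = build_awm(res, AWMConfig(key_trait="KEY"))
        # both v1 (p=0.0004) and v2 (p=0.0006) associate with KEY only
        gene_map = pd.Series({"v1": "G", "v2": "G"})
        table, _ = select_snp_per_gene(awm, gene_map)
        assert table.loc[0, "variant_id"] == "v1"

    def test_single_variant_gene(self, toy_gwas_results):
        awm = build_awm(toy_gwas_results, AWMConfig(key_trait="KEY"))
        gene_map = pd.Series({"v1": "Ga", "v2": "Gb"})
        table, _ = select_snp_per_gene(awm, gene_map)
        assert set(table["gene_id"]) == {"Ga", "Gb"}

    def test_unassigned_variants_reported(self, toy_gwas_results):
        awm = build_awm(toy_gwas_results, AWMConfig(key_trait="KEY"))
        table, unassigned = select_snp_per_gene(awm, pd.Series({"v1": "G"}))
        assert unassigned == ["v2"]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_selection_oracle(self, seed):
        results, meta = random_instance(seed + 100, n_var=20)
        cfg = AWMConfig(key_trait="T0")
        awm = build_awm(results, cfg)
        if awm.is_empty():
            return
        rng = np.random.default_rng(seed)
        genes = [f"G{k}" for k in range(5)]
        gene_of = {
            v: genes[rng.integers(0, 5)]
            for v in awm.z.index
            if rng.uniform() < 0.8
        }
        table, unassigned = select_snp_per_gene(awm, pd.Series(gene_of))
        rows, retained, _ = awm_oracle(results, cfg)
        meta_map = {
            r.variant_id: (r.chrom, r.pos) for r in meta.itertuples()
        }
        expected = gene_selection_oracle(
            rows, retained, results, cfg, gene_of, meta_map
        )
        got = {
            r.gene_id: (
                r.variant_id,
                r.n_traits_associated,
                tuple(r.traits.split(",")),
                r.cum_p,
            )
            for r in table.itertuples()
        }
        assert set(got) == set(expected)
        for gene in expected:
            assert got[gene][0] == expected[gene][0]
            assert got[gene][1] == expected[gene][1]
            assert got[gene][3] == pytest.approx(expected[gene][3])


class TestSummarize:
    def test_partition_identity(self, toy_gwas_results):
        awm = build_awm(toy_gwas_results, AWMConfig(key_trait="KEY"))
        table, _ = select_snp_per_gene(awm, pd.Series({"v1": "Ga", "v2": "Gb"}))
        s = summarize_network(table, "KEY")
        assert (
            s["n_key_only"] + s["n_key_and_other"] + s["n_other_only"]
            == s["n_genes_total"]
        )

    def test_empty_selection_all_zero(self):
        s = summarize_network(pd.DataFrame(columns=["gene_id", "traits"]), "RFI")
        assert s["n_genes_total"] == 0
        assert s["n_key_only"] == s["n_key_and_other"] == s["n_other_only"] == 0

    def test_hand_enumerated_counts(self):
        sel = pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3", "g4"],
                "traits": ["RFI", "RFI,FE", "FE,FI", "RFI,FE,FI"],
            }
        )
        s = summarize_network(sel, "RFI")
        assert s["n_key_only"] == 1
        assert s["n_key_and_other"] == 2
        assert s["n_other_only"] == 1
        assert s["genes_per_trait"] == {"FE": 3, "FI": 2, "RFI": 3}


def test_correlated_key_traits_share_more_genes():
    """AWM runs keyed on strongly genetically correlated traits select
    more overlapping genes than runs keyed on weakly correlated traits
    (majority direction over seeds)."""
    from feednet import (
        SimConfig,
        compute_grm,
        fit_null_reml,
        precorrect_phenotypes,
        run_mlma,
        simulate_annotation,
        simulate_population,
    )
    from feednet.gwas import GRMEigen
    from feednet.phenotypes import derive_traits

    corr = pd.DataFrame(
        [[1.0, 0.1, 0.1], [0.1, 1.0, 0.9], [0.1, 0.9, 1.0]],
        index=["FI", "ADG", "FW"], columns=["FI", "ADG", "FW"],
    )
    wins = 0
    n_seeds = 10
    for seed in range(n_seeds):
        cfg = SimConfig(
            n_individuals=400, n_variants=1200, n_causal=25,
            genetic_corr=corr, n_chromosomes=4, n_years=4, seed=300 + seed,
        )
        pop = simulate_population(cfg)
        traits = derive_traits(pop.traits)
        corrected = precorrect_phenotypes(traits)
        grm = compute_grm(pop.genotypes)
        eig = GRMEigen(grm)
        results = {}
        for t in ("FI", "ADG", "FW"):
            y = corrected[t].to_numpy(dtype=float)
            vc = fit_null_reml(y, eig)
            results[t] = run_mlma(pop.genotypes, y, eig, vc)
        ann = simulate_annotation(pop.genotypes, 60, 0.5, seed=seed)
        tables = {}
        for key in ("FI", "ADG", "FW"):
            awm = build_awm(results, AWMConfig(key_trait=key, p_threshold=0.01,
                                               min_other_traits=1))
            if awm.is_empty():
                tables[key] = set()
                continue
            gene_map = assign_genes(awm.variants.reset_index(), ann)
            table, _ = select_snp_per_gene(awm, gene_map)
            tables[key] = set(table["gene_id"])
        strong = len(tables["ADG"] & tables["FW"])  # r_g = 0.9
        weak = len(tables["ADG"] & tables["FI"])    # r_g = 0.1
        if strong > weak:
            wins += 1
        elif strong == weak:
            wins += 0.5
    assert wins > n_seeds / 2
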