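"""PRS engine checks against brute-force oracles and small closed forms."""

import numpy as np
import pandas as pd
import pytest

import twinprs as tp
from twinprs.config import PrsConfig
from twinprs.panel import GenotypePanel
from twinprs.prs import PrsError, PrsMatrix


def toy_panel(dosages, ref_alt=None, pos=None, mafs=None, infos=None):
    dosages = np.asarray(dosages, dtype=float)
    n_ind, n_var = dosages.shape
    ref_alt = ref_alt or [("A", "G")] * n_var
    variants = pd.DataFrame({
        "variant_id": [f"v{j}" for j in range(n_var)],
        "chrom": "1",
        "pos": pos if pos is not None else (np.arange(n_var) + 1) * 1000,
        "ref": [ra[0] for ra in ref_alt],
        "alt": [ra[1] for ra in ref_alt],
        "maf": mafs if mafs is not None else [0.3] * n_var,
        "info": infos if infos is not None else [0.99] * n_var,
    })
    return GenotypePanel(variants=variants, dosages=dosages,
                         samples=[f"s{i}" for i in range(n_ind)])


def toy_stats(panel, betas, ps, effect_is_alt=True, infos=None):
    v = panel.variants
    return pd.DataFrame({
        "variant_id": v["variant_id"],
        "chrom": v["chrom"], "pos": v["pos"],
        "effect_allele": v["alt"] if effect_is_alt else v["ref"],
        "other_allele": v["ref"] if effect_is_alt else v["alt"],
        "beta": betas, "p": ps,
        "info": infos if infos is not None else v["info"],
        "maf": v["maf"],
    })


class TestHarmonize:
    def test_ambiguous_snp_excluded_and_counted(self):
        panel = toy_panel(np.zeros((3, 10)),
                          ref_alt=[("A", "T")] + [("A", "G")] * 9)
        stats = toy_stats(panel, betas=[0.1] * 10, ps=[0.5] * 10)
        harm = tp.harmonize(stats, panel, PrsConfig())
        assert harm.n_retained == 9
        assert harm.qc_report["ambiguous"] == 1

    def test_info_filter_keeps_boundary_value(self):
        panel = toy_panel(np.zeros((3, 2)))
        stats = toy_stats(panel, betas=[0.1, 0.1], ps=[0.5, 0.5],
                          infos=[0.79, 0.80])
        harm = tp.harmonize(stats, panel, PrsConfig())
        assert harm.qc_report["low_info"] == 1
        assert list(harm.table["variant_id"]) == ["v1"]

    def test_flipped_effect_allele_negates_beta_and_scores_match_oracle(self):
        dos = np.array([[0.0, 2.0], [1.0, 1.0], [2.0, 0.0]])
        panel = toy_panel(dos)
        stats = toy_stats(panel, betas=[0.3, 0.2], ps=[0.01, 0.02],
                          effect_is_alt=False)  # effect allele is target REF
        harm = tp.harmonize(stats, panel, PrsConfig())
        assert np.allclose(harm.table["beta"], [-0.3, -0.2])
        mat = tp.score_prs(panel, list(harm.table["variant_id"]), harm,
                           PrsConfig(thresholds=(1.0,)))
        # scoring the flipped dosages with the original weights differs only
        # by the constant 2*sum(beta), which standardization removes
        oracle = (2.0 - dos) @ np.array([0.3, 0.2])
        got = mat.scores["prs_1"].to_numpy()
        assert np.allclose(got - got.mean(), oracle - oracle.mean())

    def test_duplicate_variant_id_names_offender(self):
        panel = toy_panel(np.zeros((2, 2)))
        stats = toy_stats(panel, betas=[0.1, 0.1], ps=[0.5, 0.5])
        stats.loc[1, "variant_id"] = "v0"
        with pytest.raises(PrsError, match="v0"):
            tp.harmonize(stats, panel, PrsConfig())

    def test_exclusion_counts_partition_the_input(self):
        rng = np.random.default_rng(0)
        panel = toy_panel(rng.integers(0, 3, size=(5, 30)).astype(float),
                          ref_alt=[("A", "T")] * 3 + [("C", "CT")] * 2
                                  + [("A", "G")] * 25)
        stats = toy_stats(panel, betas=rng.normal(size=30),
                          ps=rng.uniform(1e-6, 1, 30),
                          infos=np.r_[np.full(10, 0.5), np.full(20, 0.95)])
        stats.loc[29, "variant_id"] = "absent"
        harm = tp.harmonize(stats, panel, PrsConfig())
        qc = harm.qc_report
        assert sum(qc.values()) == 30
        assert qc["not_in_target"] == 1

    def test_involution_flipping_target_alleles_leaves_scores_invariant(self):
        rng = np.random.default_rng(1)
        dos = rng.integers(0, 3, size=(8, 12)).astype(float)
        panel = toy_panel(dos)
        stats = toy_stats(panel, betas=rng.normal(size=12),
                          ps=rng.uniform(1e-6, 1, 12))
        cfg = PrsConfig(thresholds=(0.5, 1.0))
        flipped = GenotypePanel(
            variants=panel.variants.assign(ref=panel.variants["alt"],
                                           alt=panel.variants["ref"]),
            dosages=2.0 - dos, samples=panel.samples)
        results = []
        for p in (panel, flipped):
            harm = tp.harmonize(stats, p, cfg)
            mat = tp.score_prs(p, list(harm.table["variant_id"]), harm, cfg)
            # allele orientation shifts each column by a constant only
            results.append(mat.scores - mat.scores.mean(axis=0))
        pd.testing.assert_frame_equal(results[0], results[1], atol=1e-12)


def clump_oracle(table, panel, cfg):
    """Independent greedy re-derivation used to audit ld_clump."""
    recs = table.sort_values(["p", "pos", "variant_id"]).to_dict("records")
    idx = panel.variant_index()
    kept, removed = [], set()
    for rec in recs:
        if rec["variant_id"] in removed:
            continue
        kept.append(rec)
        for other in recs:
            if other["variant_id"] in removed or other["variant_id"] == rec["variant_id"]:
                continue
            if any(other["variant_id"] == k["variant_id"] for k in kept):
                continue
            if abs(other["pos"] - rec["pos"]) <= cfg.clump_window_bp:
                a = panel.dosages[:, idx[rec["variant_id"]]]
                b = panel.dosages[:, idx[other["variant_id"]]]
                if np.corrcoef(a, b)[0, 1] ** 2 > cfg.clump_r2:
                    removed.add(other["variant_id"])
    return sorted((k["variant_id"] for k in kept),
                  key=lambda v: int(table.set_index("variant_id").loc[v, "pos"]))


class TestClump:
    def test_perfectly_correlated_pair_keeps_smaller_p(self):
        dos = np.tile(np.array([[0.0], [1.0], [2.0], [1.0]]), (1, 2))
        panel = toy_panel(dos, pos=[1000, 11_000])
        stats = toy_stats(panel, betas=[0.1, 0.1], ps=[1e-4, 1e-8])
        harm = tp.harmonize(stats, panel, PrsConfig())
        assert tp.ld_clump(harm, panel, PrsConfig()) == ["v1"]

    def test_uncorrelated_variants_all_retained(self):
        rng = np.random.default_rng(2)
        dos = rng.integers(0, 3, size=(400, 5)).astype(float)
        panel = toy_panel(dos)
        stats = toy_stats(panel, betas=[0.1] * 5, ps=rng.uniform(size=5))
        harm = tp.harmonize(stats, panel, PrsConfig())
        assert len(tp.ld_clump(harm, panel, PrsConfig())) == 5

    def test_block_ld_fixture_matches_exhaustive_oracle(self):
        cfg = tp.SimConfig(seed=13, n_variants=50, n_blocks=5, block_ld=0.9,
                           n_reference=300, n_pairs=2,
                           ambiguous_fraction=0, indel_fraction=0,
                           info_low_fraction=0, variant_spacing_bp=100_000)
        panel = tp.simulate_reference_panel(cfg)
        truth = tp.default_true_effects(cfg)
        stats = tp.simulate_summary_stats(panel, truth, cfg)
        pcfg = PrsConfig()
        harm = tp.harmonize(stats, panel, pcfg)
        result = tp.ld_clump(harm, panel, pcfg)
        assert result == clump_oracle(harm.table, panel, pcfg)
        # validity: no retained pair within the window exceeds clump_r2
        idx = panel.variant_index()
        tab = harm.table.set_index("variant_id")
        for i, a in enumerate(result):
            for b in result[i + 1:]:
                if abs(tab.loc[a, "pos"] - tab.loc[b, "pos"]) <= pcfg.clump_window_bp:
                    r2 = np.corrcoef(panel.dosages[:, idx[a]],
                                     panel.dosages[:, idx[b]])[0, 1] ** 2
                    assert r2 <= pcfg.clump_r2

    def test_missing_reference_variant_is_reported(self):
        panel = toy_panel(np.zeros((3, 2)))
        stats = toy_stats(panel, betas=[0.1, 0.1], ps=[0.5, 0.5])
        harm = tp.harmonize(stats, panel, PrsConfig())
        tiny_ref = toy_panel(np.zeros((3, 1)))
        with pytest.raises(PrsError, match="v1"):
            tp.ld_clump(harm, tiny_ref, PrsConfig())


class TestScore:
    def test_single_snp_closed_form(self):
        panel = toy_panel(np.array([[0.0, 0], [1.0, 0], [2.0, 0]]))
        stats = toy_stats(panel, betas=[0.5, 0.1], ps=[0.01, 0.9])
        harm = tp.harmonize(stats, panel, PrsConfig())
        mat = tp.score_prs(panel, ["v0"], harm, PrsConfig(thresholds=(0.05, 1.0)))
        assert np.allclose(mat.scores["prs_0.05"], [0.0, 0.5, 1.0])
        assert np.allclose(mat.scores["prs_1"], [0.0, 0.5, 1.0])

    def test_threshold_below_all_p_gives_empty_column(self):
        panel = toy_panel(np.ones((3, 2)))
        stats = toy_stats(panel, betas=[0.5, 0.2], ps=[0.5, 0.9])
        harm = tp.harmonize(stats, panel, PrsConfig())
        mat = tp.score_prs(panel, ["v0", "v1"], harm,
                           PrsConfig(thresholds=(0.001, 1.0)))
        assert mat.n_snps["prs_0.001"] == 0
        assert np.all(mat.scores["prs_0.001"] == 0)

    def test_random_fixture_equals_double_loop_oracle_exactly(self):
        rng = np.random.default_rng(3)
        dos = rng.integers(0, 3, size=(10, 20)).astype(float)
        panel = toy_panel(dos)
        betas = rng.normal(size=20)
        ps = rng.uniform(1e-6, 1, 20)
        stats = toy_stats(panel, betas=betas, ps=ps)
        cfg = PrsConfig()
        harm = tp.harmonize(stats, panel, cfg)
        ids = list(harm.table["variant_id"])
        mat = tp.score_prs(panel, ids, harm, cfg)
        for t in cfg.thresholds:
            for i in range(10):
                expected = sum(betas[j] * dos[i, j] for j in range(20)
                               if ps[j] <= t)
                assert mat.scores.loc[f"s{i}", f"prs_{t:g}"] == pytest.approx(
                    expected, abs=1e-12)

    def test_monotone_inclusion_across_thresholds(self, scored):
        n = scored["matrix"].n_snps
        assert (n.diff().dropna() >= 0).all()

    def test_missing_dosages_are_mean_imputed(self):
        dos = np.array([[0.0], [2.0], [np.nan]])
        panel = toy_panel(dos)
        stats = toy_stats(panel, betas=[1.0], ps=[0.5])
        harm = tp.harmonize(stats, panel, PrsConfig())
        mat = tp.score_prs(panel, ["v0"], harm, PrsConfig(thresholds=(1.0,)))
        assert mat.scores["prs_1"].tolist() == [0.0, 2.0, 1.0]


class TestPcPrs:
    def _matrix(self, arr, names=None):
        arr = np.asarray(arr, dtype=float)
        names = names or [f"prs_{i}" for i in range(arr.shape[1])]
        return PrsMatrix(
            scores=pd.DataFrame(arr, columns=names),
            n_snps=pd.Series({c: 5 for c in names}))

    def test_identical_columns_are_degenerate_pc(self):
        rng = np.random.default_rng(4)
        col = rng.normal(size=50)
        mat = self._matrix(np.tile(col[:, None], (1, 8)))
        res = tp.pc_prs(mat)
        assert res.variance_explained == pytest.approx(1.0)
        assert np.allclose(np.abs(res.loadings), 1 / np.sqrt(8))
        z = (col - col.mean()) / col.std(ddof=0)
        assert np.allclose(res.score, z)

    def test_two_orthogonal_columns_split_variance(self):
        n = 400
        a = np.r_[np.ones(n // 2), -np.ones(n // 2)]
        b = np.r_[np.ones(n // 4), -np.ones(n // 2), np.ones(n // 4)]
        assert abs(a @ b) < 1e-9
        res = tp.pc_prs(self._matrix(np.c_[a, b]))
        assert res.variance_explained == pytest.approx(0.5)

    def test_pc1_beats_single_columns_and_random_combinations(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(200, 1))
        arr = base + 0.5 * rng.normal(size=(200, 8))
        mat = self._matrix(arr)
        res = tp.pc_prs(mat)
        z = mat.standardize().scores.to_numpy()
        var_pc = np.var(z @ res.loadings.to_numpy())
        for j in range(8):
            e = np.zeros(8)
            e[j] = 1.0
            assert var_pc >= np.var(z @ e) - 1e-9
        w = rng.normal(size=(1000, 8))
        w /= np.linalg.norm(w, axis=1, keepdims=True)
        assert (np.var(z @ w.T, axis=0) <= var_pc + 1e-9).all()

    def test_degenerate_columns_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        arr = rng.normal(size=(50, 3))
        mat = PrsMatrix(scores=pd.DataFrame(arr, columns=["a", "b", "c"]),
                        n_snps=pd.Series({"a": 0, "b": 5, "c": 5}))
        with pytest.warns(UserWarning, match="degenerate"):
            res = tp.pc_prs(mat)
        assert list(res.loadings.index) == ["b", "c"]

    def test_fewer_than_two_usable_columns_fails(self):
        mat = PrsMatrix(scores=pd.DataFrame({"a": [1.0, 2], "b": [0.0, 0]}),
                        n_snps=pd.Series({"a": 3, "b": 0}))
        with pytest.raises(PrsError):
            tp.pc_prs(mat)

    def test_sign_convention_follows_most_inclusive_column(self, scored):
        res = scored["pcprs"]
        full = scored["matrix"].scores["prs_1"]
        assert np.corrcoef(res.score, full)[0, 1] > 0


class TestAncestryPcs:
    def test_two_population_fixture_separates_on_pc1(self):
        rng = np.random.default_rng(7)
        n_per, n_var = 120, 60
        f1 = rng.uniform(0.1, 0.4, n_var)
        f2 = np.clip(f1 + rng.choice([-1, 1], n_var) * 0.3, 0.05, 0.95)
        dos = np.r_[rng.binomial(2, f1, size=(n_per, n_var)),
                    rng.binomial(2, f2, size=(n_per, n_var))].astype(float)
        panel = toy_panel(dos)
        cohort = pd.DataFrame({
            "individual_id": panel.samples,
            "family_id": [f"f{i}" for i in range(2 * n_per)],
        })
        pcs = tp.ancestry_pcs(panel, cohort, k=2)
        label = np.r_[np.zeros(n_per), np.ones(n_per)]
        assert abs(np.corrcoef(pcs["PC1"], label)[0, 1]) > 0.9

    def test_mz_cotwins_project_identically(self, small_sim, scored):
        cohort = small_sim.cohort
        pcs = scored["pcs"].to_numpy()
        mz = cohort.index[cohort["zygosity"] == "MZ"].to_numpy()
        assert np.allclose(pcs[mz[::2]], pcs[mz[1::2]])

    def test_rank_deficient_panel_fails(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=(6, 3))
        dos = np.c_[base, base][:, :5]  # rank <= 3
        panel = toy_panel(dos, pos=[10_000_000 * (i + 1) for i in range(5)])
        cohort = pd.DataFrame({"individual_id": panel.samples,
                               "family_id": [f"f{i}" for i in range(6)]})
        with pytest.raises(PrsError, match="rank"):
            tp.ancestry_pcs(panel, cohort, k=6)
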