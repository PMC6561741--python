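"""NB Wald differential testing: calibration, recovery, invariances."""

import numpy as np
import pandas as pd
import pytest

from spikecal import differential as de
from spikecal import simulate as sim
from spikecal.calibration import spikein_size_factors


def _matrix(rng, mu_unt, mu_trt, phi=0.05, n=3):
    cols = {}
    for r in range(1, n + 1):
        cols[f"untreated_rep{r}"] = sim.nb_counts(rng, mu_unt, phi)
    for r in range(1, n + 1):
        cols[f"treated_rep{r}"] = sim.nb_counts(rng, mu_trt, phi)
    return pd.DataFrame(cols)


def _condition(columns):
    return {c: ("treated" if c.startswith("treated") else "untreated")
            for c in columns}


def _unit_sf(columns):
    return {c: 1.0 for c in columns}


class TestDispersion:
    def test_poisson_counts_estimate_near_floor_before_moderation(self):
        rng = np.random.default_rng(0)
        counts = _matrix(rng, np.full(2_000, 100.0), np.full(2_000, 100.0),
                         phi=0.0, n=10)
        phi = de.estimate_dispersion(counts, _unit_sf(counts.columns),
                                     _condition(counts.columns),
                                     prior_df=0.0)
        assert np.median(phi) < 0.01

    def test_nb_dispersion_recovered_at_many_replicates(self):
        rng = np.random.default_rng(1)
        counts = _matrix(rng, np.full(500, 100.0), np.full(500, 100.0),
                         phi=0.1, n=50)
        phi = de.estimate_dispersion(counts, _unit_sf(counts.columns),
                                     _condition(counts.columns))
        inside = (phi >= 0.05) & (phi <= 0.2)
        assert inside.mean() >= 0.9

    def test_constant_counts_fall_to_floor(self):
        counts = pd.DataFrame({c: [7, 7] for c in
                               ["untreated_rep1", "untreated_rep2",
                                "treated_rep1", "treated_rep2"]})
        phi = de.estimate_dispersion(counts, _unit_sf(counts.columns),
                                     _condition(counts.columns), prior_df=0.0)
        np.testing.assert_allclose(phi, de.PHI_FLOOR)

    def test_single_replicate_refused(self):
        counts = pd.DataFrame({"untreated_rep1": [1],
                               "treated_rep1": [2],
                               "treated_rep2": [3]})
        with pytest.raises(ValueError, match="replicates"):
            de.estimate_dispersion(counts, _unit_sf(counts.columns),
                                   _condition(counts.columns))


class TestWaldTest:
    def test_identical_means_give_null_result(self):
        counts = pd.DataFrame({
            "untreated_rep1": [100], "untreated_rep2": [100],
            "treated_rep1": [100], "treated_rep2": [100]})
        res = de.nb_wald_test(counts, _unit_sf(counts.columns),
                              _condition(counts.columns), dispersions=0.05)
        assert res.at[0, "log2FC"] == 0.0
        assert res.at[0, "p"] == pytest.approx(1.0)

    def test_planted_fourfold_recovered(self):
        rng = np.random.default_rng(2)
        counts = _matrix(rng, np.full(100, 200.0), np.full(100, 800.0))
        res = de.nb_wald_test(counts, _unit_sf(counts.columns),
                              _condition(counts.columns))
        assert res["log2FC"].mean() == pytest.approx(2.0, abs=0.2)
        assert res["significant_up"].mean() >= 0.9

    def test_null_fdr_controlled(self):
        rng = np.random.default_rng(3)
        mu = rng.lognormal(np.log(200), 1.0, 5_000)
        counts = _matrix(rng, mu, mu)
        res = de.nb_wald_test(counts, _unit_sf(counts.columns),
                              _condition(counts.columns))
        frac = (res["significant_up"] | res["significant_down"]).mean()
        assert frac <= 0.07

    def test_all_zero_features_reported_na(self):
        rng = np.random.default_rng(4)
        counts = _matrix(rng, np.full(10, 50.0), np.full(10, 50.0))
        counts.iloc[0] = 0
        res = de.nb_wald_test(counts, _unit_sf(counts.columns),
                              _condition(counts.columns))
        assert np.isnan(res.at[0, "p"]) and np.isnan(res.at[0, "padj"])
        assert not res.at[0, "significant_up"]
        assert res["p"].notna().sum() == 9

    def test_label_swap_negates_lfc_and_preserves_p(self):
        rng = np.random.default_rng(5)
        counts = _matrix(rng, np.full(50, 100.0), np.full(50, 300.0))
        cond = _condition(counts.columns)
        swapped = {c: ("untreated" if v == "treated" else "treated")
                   for c, v in cond.items()}
        a = de.nb_wald_test(counts, _unit_sf(counts.columns), cond)
        b = de.nb_wald_test(counts, _unit_sf(counts.columns), swapped)
        np.testing.assert_allclose(b["log2FC"], -a["log2FC"])
        np.testing.assert_allclose(b["p"], a["p"])

    def test_scaling_sample_and_its_size_factor_is_invariant(self):
        rng = np.random.default_rng(6)
        counts = _matrix(rng, np.full(50, 100.0), np.full(50, 100.0))
        sf = _unit_sf(counts.columns)
        a = de.nb_wald_test(counts, sf, _condition(counts.columns))
        scaled = counts.copy()
        scaled["treated_rep1"] = scaled["treated_rep1"] * 5
        sf2 = dict(sf, treated_rep1=5.0)
        b = de.nb_wald_test(scaled, sf2, _condition(counts.columns))
        np.testing.assert_allclose(b["log2FC"], a["log2FC"])
        np.testing.assert_allclose(b["p"], a["p"])

    def test_bh_adjustment_identities(self):
        rng = np.random.default_rng(7)
        counts = _matrix(rng, np.full(400, 80.0), np.full(400, 80.0))
        res = de.nb_wald_test(counts, _unit_sf(counts.columns),
                              _condition(counts.columns)).dropna(subset=["p"])
        assert (res["padj"] >= res["p"] - 1e-12).all()
        ordered = res.sort_values("p")
        # BH adjusted values are monotone in the p-value rank
        assert (np.diff(ordered["padj"]) >= -1e-12).all()

    def test_global_shift_bias_of_naive_size_factors(self):
        """A genome-wide 5-fold depletion hitting 95% of features: spike-in
        anchored size factors center unaffected features at log2FC 0, while
        naive total-count factors displace the mode — the artifact spike-in
        calibration exists to fix."""
        rng = np.random.default_rng(8)
        n = 2_000
        affected = rng.random(n) < 0.95
        mu = rng.lognormal(np.log(300), 0.4, n)
        mu_trt = mu * np.where(affected, 0.2, 1.0)
        counts = _matrix(rng, mu, mu_trt)
        cond = _condition(counts.columns)
        # spike-anchored: control features invariant across conditions
        spike = pd.DataFrame(
            {c: sim.nb_counts(rng, np.full(200, 500.0), 0.05)
             for c in counts.columns})
        sf_spike = spikein_size_factors(spike, {c: 0.4 for c in counts.columns})
        sf_naive = de.total_count_size_factors(counts)
        res_spike = de.nb_wald_test(counts, sf_spike, cond)
        res_naive = de.nb_wald_test(counts, sf_naive, cond)
        mode_spike = np.median(res_spike.loc[~affected, "log2FC"])
        mode_naive = np.median(res_naive.loc[~affected, "log2FC"])
        assert abs(mode_spike) < 0.2
        assert abs(mode_naive) > 0.5


class TestSignificanceCall:
    @pytest.fixture()
    def frame(self):
        return pd.DataFrame({
            "feature_id": ["a", "b", "c", "d"],
            "base_mean": [10.0] * 4,
            "log2FC": [np.log2(1.4), np.log2(1.6), np.log2(1.2),
                       -np.log2(1.8)],
            "se": [0.1] * 4,
            "p": [0.01] * 4,
            "padj": [0.04, 0.04, 0.04, 0.04],
        })

    def test_rna_mode_requires_fold_change(self, frame):
        out = de.significance_call(frame, mode="rna")
        assert not out.at[0, "significant_up"]      # FC 1.4 < 1.5
        assert out.at[1, "significant_up"]          # FC 1.6
        assert not out.at[2, "significant_up"]      # FC 1.2
        assert out.at[3, "significant_down"]        # FC 1/1.8

    def test_chip_mode_ignores_fold_change(self, frame):
        out = de.significance_call(frame, mode="chip")
        assert out.at[2, "significant_up"]          # padj alone decides

    def test_padj_above_threshold_never_significant(self, frame):
        frame["padj"] = 0.2
        out = de.significance_call(frame, mode="chip")
        assert not out[["significant_up", "significant_down"]].any().any()


class TestMaTable:
    def test_projection_preserves_flags_and_row_count(self):
        rng = np.random.default_rng(9)
        counts = _matrix(rng, np.full(30, 100.0), np.full(30, 400.0))
        res = de.nb_wald_test(counts, _unit_sf(counts.columns),
                              _condition(counts.columns))
        ma = de.ma_table(res)
        assert len(ma) == res["p"].notna().sum()
        assert ma["significant"].sum() == (res["significant_up"]
                                           | res["significant_down"]).sum()
        assert (np.diff(ma["base_mean"]) >= 0).all()

    def test_empty_input_gives_empty_table(self):
        empty = pd.DataFrame(columns=de.RESULT_COLUMNS)
        assert len(de.ma_table(empty)) == 0


def test_rna_pipeline_recovers_planted_upfold():
    """End-to-end: simulated RNA experiment with 4-fold derepression of
    Polycomb-target genes; spike-anchored calibrated log2FC centers on 2."""
    genes = sim.make_gene_table(800, pcg_fraction=0.3, seed=10)
    scen = sim.RnaScenario("derepression", {"PcG_target": 4.0})
    res = sim.simulate_rna_experiment(genes, scen, depth=2_000_000, seed=10)
    ratios = {lib.sample_id: lib.mixing_ratio for lib in res.libraries}
    sf = spikein_size_factors(res.spike_counts, ratios)
    cond = {lib.sample_id: lib.condition for lib in res.libraries}
    out = de.nb_wald_test(res.counts, sf, cond)
    out = de.significance_call(out, mode="rna")
    is_target = (genes.set_index("gene_id")["gene_class"]
                 == "PcG_target").reindex(out["feature_id"]).to_numpy()
    assert out.loc[is_target, "log2FC"].mean() == pytest.approx(2.0, abs=0.2)
    assert out.loc[~is_target, "log2FC"].mean() == pytest.approx(0.0, abs=0.1)
    assert out.loc[is_target, "significant_up"].mean() >= 0.9
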