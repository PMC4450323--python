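"""Tests for deconvolution, adjustment, scores and paired progression testing."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from oracles import signed_rank_enum
from progressionkit.methylation import (BetaMatrix, CELL_TYPES, ReferencePanel,
                                        adjust_for_composition,
                                        b_cell_orientation, b_cell_score,
                                        change_magnitude_summary, deconvolve,
                                        deconvolve_samples,
                                        paired_progression_test,
                                        progression_score,
                                        quantile_change_enrichment,
                                        signed_rank_test)


@pytest.fixture(scope="module")
def panel():
    rng = np.random.default_rng(0)
    n = 40
    profiles = {}
    for i, ct in enumerate(CELL_TYPES):
        col = rng.uniform(0.1, 0.9, n)
        col[i * 8:(i + 1) * 8] = 0.95 if i % 2 == 0 else 0.05  # markers
        profiles[ct] = col
    idx = pd.Index([f"cg{i:04d}" for i in range(n)], name="cpg_id")
    return ReferencePanel(pd.DataFrame(profiles, index=idx))


class TestDeconvolve:
    def test_pure_reference_column_recovered_exactly(self, panel):
        w = deconvolve(panel.profiles["B"], panel)
        assert w == pytest.approx([1, 0, 0, 0, 0], abs=1e-9)

    def test_two_component_mixture_recovered(self, panel):
        beta = 0.6 * panel.profiles["B"] + 0.4 * panel.profiles["CD4T"]
        w = deconvolve(beta, panel)
        assert w == pytest.approx([0.6, 0, 0.4, 0, 0], abs=1e-6)

    def test_mixture_beats_dense_grid_search(self, panel):
        # grid over the B/CD4T face of the simplex at step 0.001: the
        # constrained-LS solution must be at least as good as every grid point
        beta = (0.55 * panel.profiles["B"] + 0.45 * panel.profiles["CD4T"]).to_numpy()
        R = panel.profiles.to_numpy()
        w = deconvolve(pd.Series(beta, index=panel.marker_ids), panel)
        resid = np.sum((R @ w - beta) ** 2)
        grid = np.arange(0, 1.0001, 0.001)
        cand = np.zeros((len(grid), 5))
        cand[:, 0] = grid
        cand[:, 2] = 1 - grid
        grid_best = np.min(np.sum((cand @ R.T - beta) ** 2, axis=1))
        assert resid <= grid_best + 1e-12

    def test_symmetric_reference_gives_uniform_weights(self):
        # identical columns are rank-deficient (indistinguishable): error
        idx = pd.Index([f"cg{i}" for i in range(10)])
        prof = pd.DataFrame({ct: np.full(10, 0.5) for ct in CELL_TYPES}, index=idx)
        with pytest.raises(ValueError, match="rank-deficient"):
            deconvolve(pd.Series(0.5, index=idx), ReferencePanel(prof))

    def test_missing_markers_named(self, panel):
        beta = panel.profiles["B"].iloc[:-3]
        with pytest.raises(ValueError, match="missing marker"):
            deconvolve(beta, panel)

    def test_output_on_simplex_under_noise(self, panel, rng):
        for _ in range(10):
            w_true = rng.dirichlet(np.ones(5))
            beta = panel.profiles.to_numpy() @ w_true + rng.normal(0, 0.05, len(panel.profiles))
            w = deconvolve(pd.Series(np.clip(beta, 0, 1), index=panel.marker_ids), panel)
            assert (w >= 0).all()
            assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_noiseless_recovery_max_norm(self, panel, rng):
        for _ in range(10):
            w_true = rng.dirichlet(np.ones(5))
            beta = panel.profiles.to_numpy() @ w_true
            w = deconvolve(pd.Series(beta, index=panel.marker_ids), panel)
            assert np.abs(w - w_true).max() < 1e-6


class TestAdjustForComposition:
    def _cohort(self, rng, n_samples=12, n_cpgs=30, confounded=True):
        comps = rng.dirichlet(np.ones(5) * 3, size=n_samples)
        comps = pd.DataFrame(comps, columns=list(CELL_TYPES),
                             index=[f"s{i}" for i in range(n_samples)])
        base = rng.uniform(0.2, 0.8, n_cpgs)
        B = np.tile(base[:, None], (1, n_samples))
        if confounded:
            B = B + 0.3 * (comps["B"].to_numpy()[None, :] - comps["B"].mean())
        betas = pd.DataFrame(np.clip(B, 0, 1), columns=comps.index,
                             index=[f"cg{i}" for i in range(n_cpgs)])
        return betas, comps

    def test_identical_compositions_leave_betas_unchanged(self, rng):
        betas, comps = self._cohort(rng, confounded=False)
        same = pd.DataFrame(np.tile(np.full(5, 0.2), (len(comps), 1)),
                            columns=list(CELL_TYPES), index=comps.index)
        out = adjust_for_composition(betas, same)
        pd.testing.assert_frame_equal(out, betas, atol=1e-10, rtol=0)

    def test_perfectly_linear_signal_flattens_to_grand_mean(self, rng):
        betas, comps = self._cohort(rng, confounded=True)
        # make beta *exactly* linear in B proportion
        lin = 0.3 + 0.4 * comps["B"].to_numpy()
        betas.iloc[0] = lin
        out = adjust_for_composition(betas, comps)
        assert out.iloc[0].to_numpy() == pytest.approx(
            np.full(len(comps), lin.mean()), abs=1e-10)

    def test_adjustment_is_idempotent(self, rng):
        betas, comps = self._cohort(rng)
        once = adjust_for_composition(betas, comps)
        twice = adjust_for_composition(once, comps)
        assert np.abs(twice.to_numpy() - once.to_numpy()).max() < 1e-10

    def test_output_stays_in_unit_interval(self, rng):
        betas, comps = self._cohort(rng)
        out = adjust_for_composition(betas, comps)
        assert out.to_numpy().min() >= 0 and out.to_numpy().max() <= 1

    def test_bad_composition_sum_rejected(self, rng):
        betas, comps = self._cohort(rng)
        comps.iloc[0] = comps.iloc[0] * 0.8
        with pytest.raises(ValueError, match="sum to 1"):
            adjust_for_composition(betas, comps)

    def test_too_few_samples_rejected(self, rng):
        betas, comps = self._cohort(rng, n_samples=4)
        with pytest.raises(ValueError, match="samples"):
            adjust_for_composition(betas, comps)


class TestBCellScore:
    def test_identical_vectors_score_zero(self):
        v = pd.Series([0.2, 0.5, 0.8], index=list("abc"))
        assert b_cell_score(v, v, list("abc")) == 0.0

    def test_constant_shift(self):
        v1 = pd.Series([0.2, 0.5, 0.8], index=list("abc"))
        assert b_cell_score(v1, v1 + 0.1, list("abc")) == pytest.approx(0.1)

    def test_empty_sites_rejected(self):
        v = pd.Series([0.2], index=["a"])
        with pytest.raises(ValueError):
            b_cell_score(v, v, [])

    def test_score_tracks_purity_change_across_patients(self, panel, rng):
        # 50 patients with known B-fraction changes; the oriented score must
        # correlate strongly with the change in B-cell load
        R = panel.profiles.to_numpy()
        orientation = b_cell_orientation(panel, panel.marker_ids)
        scores, shifts = [], []
        for _ in range(50):
            b1 = rng.uniform(0.5, 0.95)
            b2 = rng.uniform(0.5, 0.95)
            rest1 = rng.dirichlet(np.ones(4)) * (1 - b1)
            rest2 = rng.dirichlet(np.ones(4)) * (1 - b2)
            beta1 = R @ np.concatenate([[b1], rest1]) + rng.normal(0, 0.01, len(R))
            beta2 = R @ np.concatenate([[b2], rest2]) + rng.normal(0, 0.01, len(R))
            s = b_cell_score(pd.Series(beta1, index=panel.marker_ids),
                             pd.Series(beta2, index=panel.marker_ids),
                             panel.marker_ids, orientation=orientation)
            scores.append(s)
            shifts.append(b2 - b1)
        assert spearmanr(scores, shifts).statistic > 0.9


class TestSignedRank:
    def test_all_zero_differences_p_one(self):
        assert signed_rank_test(np.zeros(27)) == 1.0

    def test_six_positive_distinct_exact(self):
        assert signed_rank_test([0.1, 0.2, 0.3, 0.4, 0.5, 0.6]) == pytest.approx(2 / 64)

    @pytest.mark.parametrize("n", range(5, 13))
    def test_matches_sign_flip_enumeration(self, n, rng):
        for _ in range(5):
            d = rng.normal(0.02, 0.05, n)
            d = d[d != 0]
            while np.unique(np.abs(d)).size != d.size:  # pragma: no cover
                d = rng.normal(0.02, 0.05, n)
            assert signed_rank_test(d) == pytest.approx(
                signed_rank_enum(d), abs=1e-12)


class TestPairedProgression:
    def _beta_matrix(self, deltas, n_patients=8, base=0.4, rng=None):
        """Build a paired BetaMatrix with the given per-CpG t2-t1 deltas."""
        rng = rng or np.random.default_rng(5)
        n_cpgs = len(deltas)
        idx = pd.Index([f"cg{i}" for i in range(n_cpgs)])
        values, meta = {}, []
        for p in range(n_patients):
            t1 = np.clip(base + rng.normal(0, 0.02, n_cpgs), 0, 1)
            values[f"p{p}_t1"] = t1
            values[f"p{p}_t2"] = np.clip(t1 + np.asarray(deltas), 0, 1)
            meta.append((f"p{p}_t1", f"p{p}", "t1"))
            meta.append((f"p{p}_t2", f"p{p}", "t2"))
        md = pd.DataFrame(meta, columns=["sample_id", "patient_id", "timepoint"]
                          ).set_index("sample_id")
        return BetaMatrix(pd.DataFrame(values, index=idx), md)

    def test_all_zero_deltas_untested(self):
        bm = self._beta_matrix([0.0] * 5)
        out = paired_progression_test(bm)
        assert out["untested"].all()
        assert (out["wilcoxon_p"] == 1.0).all()
        assert not out["significant"].any()

    def test_planted_shift_found_with_direction(self):
        deltas = [0.15] * 3 + [-0.15] * 2 + [0.0] * 45
        bm = self._beta_matrix(deltas, n_patients=12)
        out = paired_progression_test(bm).set_index("cpg_id")
        assert out.loc["cg0", "significant"] and out.loc["cg0", "direction"] == "up"
        assert out.loc["cg3", "significant"] and out.loc["cg3", "direction"] == "down"
        null_sig = out.iloc[5:]["significant"].sum()
        assert null_sig == 0  # null CpGs have tiny noise-only deltas

    def test_min_pairs_enforced(self):
        bm = self._beta_matrix([0.1] * 4, n_patients=5)
        out = paired_progression_test(bm, min_pairs=6)
        assert out["untested"].all()

    def test_paired_structure_validated(self):
        bm = self._beta_matrix([0.1] * 4, n_patients=6)
        bm.metadata.loc["p0_t2", "timepoint"] = "t1"
        with pytest.raises(ValueError, match="multiple t1|exactly one"):
            paired_progression_test(bm)


class TestScoresAndSummaries:
    def test_progression_score_examples(self, rng):
        v1 = pd.Series([0.3, 0.5], index=["a", "b"])
        assert progression_score(v1, v1, ["a", "b"]) == 0.0
        v2 = pd.Series([0.4, 0.4], index=["a", "b"])
        assert progression_score(v1, v2, ["a", "b"]) == pytest.approx(0.2)
        with pytest.warns(UserWarning):
            assert progression_score(v1, v2, []) == 0.0
        # random vectors: equals independent recomputation
        a = pd.Series(rng.uniform(0, 1, 20), index=[f"c{i}" for i in range(20)])
        b = pd.Series(rng.uniform(0, 1, 20), index=a.index)
        assert progression_score(a, b, a.index) == pytest.approx(
            float(np.abs(b.to_numpy() - a.to_numpy()).sum()))

    def test_change_magnitude_counts(self):
        deltas = pd.DataFrame({"p1": [0.25, 0.10, 0.01], "p2": [0.06] * 3},
                              index=["a", "b", "c"])
        per_patient, means = change_magnitude_summary(deltas)
        assert per_patient.loc["p1", "n_above_0.05"] == 2
        assert per_patient.loc["p1", "n_above_0.2"] == 1
        assert per_patient.loc["p2", "n_above_0.05"] == 3
        assert per_patient.loc["p2", "n_above_0.2"] == 0
        assert means["n_above_0.05"] == pytest.approx(2.5)

    def test_quantile_enrichment_odds_ratio_arithmetic(self):
        # membership constructed so the 2x2 is a=80,b=20,c=920,d=980
        n = 2000
        deltas = pd.Series(np.linspace(-1, 1, n),
                           index=[f"c{i}" for i in range(n)])
        flagged = (deltas <= deltas.quantile(0.025)) | (deltas >= deltas.quantile(0.975))
        flag_ids = list(deltas.index[flagged])
        rest_ids = list(deltas.index[~flagged])
        members = flag_ids[:80] + rest_ids[:920]
        out = quantile_change_enrichment(deltas, {"set": members}, q=0.025)
        row = out.iloc[0]
        assert (row.a, row.b, row.c, row.d) == (80, 20, 920, 980)
        assert row.odds_ratio == pytest.approx(80 * 980 / (20 * 920), rel=1e-12)

    def test_quantile_enrichment_null_behaviour(self, rng):
        n = 1000
        deltas = pd.Series(rng.normal(0, 1, n), index=[f"c{i}" for i in range(n)])
        members = rng.choice(deltas.index, 200, replace=False)
        out = quantile_change_enrichment(deltas, {"null": members}, q=0.25)
        assert 0.5 < out.iloc[0].odds_ratio < 2.0
        assert out.iloc[0].fisher_p > 0.001

    def test_quantile_out_of_range(self):
        with pytest.raises(ValueError):
            quantile_change_enrichment(pd.Series([1.0, 2.0]), {}, q=0.7)


class TestCohortRecovery:
    def test_composition_recovery_and_effect_retention(self, small_methylation_cohort):
        """Deconvolution + adjustment on a confounded cohort: compositions
        recovered, composition-driven signal removed, planted deltas kept."""
        cfg, coh = small_methylation_cohort
        panel = coh.reference.panel
        comps = deconvolve_samples(coh.betas.values.loc[panel.marker_ids], panel)
        err = np.abs(comps.to_numpy() - coh.truth.true_compositions.to_numpy())
        assert err.mean() < 0.05

        adjusted = BetaMatrix(adjust_for_composition(coh.betas.values, comps),
                              coh.betas.metadata)
        raw_deltas = coh.betas.paired_deltas().mean(axis=1)
        deltas = adjusted.paired_deltas().mean(axis=1)
        truth = coh.truth.true_progression_cpgs
        planted_sign = pd.Series(np.where(truth["direction"] == "up", 1.0, -1.0),
                                 index=truth.index)

        # composition-driven drift removed: at marker CpGs (strong cell-type
        # contrast, no planted effect) the adjusted deltas shrink sharply
        markers = coh.reference.marker_ids
        assert deltas.loc[markers].abs().mean() < 0.4 * raw_deltas.loc[markers].abs().mean()

        # planted deltas retained: correlated with planted effects, with
        # attenuation bounded by the timepoint/composition collinearity
        recovered = deltas.loc[truth.index] * planted_sign
        assert np.corrcoef(recovered, truth["effect"])[0, 1] > 0.7
        assert recovered.mean() > 0.5 * truth["effect"].mean()
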