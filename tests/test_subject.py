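"""GLM betas, prestimulus-baseline Cohen d, coactivation matrices, and the
channel-pair / region bookkeeping."""

import numpy as np
import pytest

from vrnirs.errors import InvalidInputError
from vrnirs.hemodynamics import double_gamma_hrf
from vrnirs.preprocess import FilterParams, HemoglobinSeries
from vrnirs.protocol import Block, TaskDesign
from vrnirs.subject import (
    DEFAULT_REGION_MAP,
    FC_PAIRS,
    block_effect_size,
    build_design_matrix,
    coactivation_matrix,
    compute_subject_metrics,
    fc_index,
    fc_pair_region_label,
    fit_glm,
    region_pair_fc,
)

FS = 10.0


def _hb(hbo, valid=None):
    hbo = np.atleast_2d(hbo)
    n_ch, n_t = hbo.shape
    if valid is None:
        valid = np.ones((n_ch, n_t), bool)
    return HemoglobinSeries(hbo=hbo, hbr=-hbo / 3, valid_mask=valid,
                            dpf=np.array([6.5, 5.5]), pathlength=3.5,
                            sampling_rate=FS)


def _single_block_design(onset=30.0, duration=5.0, total=120.0):
    return TaskDesign(blocks=[Block("task", onset, duration)],
                      sampling_rate=FS, total_duration=total)


class TestDesignMatrix:
    def test_column_peaks_after_onset_by_hrf_delay(self):
        d = _single_block_design()
        X = build_design_matrix(d)
        col = X.regressors[:, 0]
        peak_t = np.argmax(col) / FS
        # block onset 30 s, 5 s block, HRF peak ~6 s after onset
        assert 34.0 < peak_t < 42.0

    def test_linearity_over_far_apart_blocks(self):
        total = 400.0
        two = TaskDesign(blocks=[Block("t", 50, 5), Block("t", 250, 5)],
                         sampling_rate=FS, total_duration=total)
        one_a = TaskDesign(blocks=[Block("t", 50, 5)], sampling_rate=FS,
                           total_duration=total)
        one_b = TaskDesign(blocks=[Block("t", 250, 5)], sampling_rate=FS,
                           total_duration=total)
        # compare unnormalized convolutions (peak-normalization rescales)
        from vrnirs.hemodynamics import condition_regressor

        sum_ab = (condition_regressor(one_a, "t", normalize=False)
                  + condition_regressor(one_b, "t", normalize=False))
        both = condition_regressor(two, "t", normalize=False)
        assert np.max(np.abs(both - sum_ab)) < 1e-10

    def test_matches_direct_summation_convolution(self):
        d = _single_block_design()
        from vrnirs.hemodynamics import condition_boxcar

        box = condition_boxcar(d, "task")
        h = double_gamma_hrf(FS)
        n = d.n_samples
        brute = np.zeros(n)
        for i in range(n):  # direct-summation oracle
            acc = 0.0
            for k in range(h.size):
                if 0 <= i - k < n:
                    acc += h[k] * box[i - k]
            brute[i] = acc
        X = build_design_matrix(d)
        col = X.regressors[:, 0] * np.max(np.abs(brute))
        assert np.max(np.abs(col - brute)) < 1e-10

    def test_empty_design_rejected(self):
        with pytest.raises(InvalidInputError):
            build_design_matrix(TaskDesign(blocks=[], sampling_rate=FS,
                                           total_duration=10.0))


class TestFitGlm:
    def test_recovers_exact_beta_on_noiseless_data(self):
        d = _single_block_design()
        X = build_design_matrix(d)
        y = 2.0 * X.regressors[:, 0] + 0.7
        glm = fit_glm(_hb(np.tile(y, (8, 1))), X)
        assert np.allclose(glm["beta"], 2.0, atol=1e-9)

    def test_pure_drift_gives_zero_condition_beta(self):
        d = _single_block_design()
        X = build_design_matrix(d)
        drift = np.linspace(0, 1, d.n_samples)
        glm = fit_glm(_hb(drift), X)
        assert abs(glm["beta"][0, 0]) < 1e-9

    def test_matches_normal_equation_oracle(self, rng):
        d = _single_block_design()
        X = build_design_matrix(d)
        y = rng.normal(size=(3, d.n_samples))
        glm = fit_glm(_hb(y), X)
        A = X.regressors
        oracle = np.linalg.solve(A.T @ A, A.T @ y.T).T  # (XtX)^-1 Xt y
        assert np.max(np.abs(glm["beta"] - oracle[:, X.condition_columns])) < 1e-8

    def test_insufficient_valid_samples_yield_nan_not_error(self):
        d = _single_block_design()
        X = build_design_matrix(d)
        valid = np.zeros((1, d.n_samples), bool)
        valid[0, :3] = True
        glm = fit_glm(_hb(np.zeros(d.n_samples), valid), X)
        assert np.isnan(glm["beta"]).all()


class TestBlockEffectSize:
    def _toy(self, delta, sigma=0.01, seed=5):
        r = np.random.default_rng(seed)
        d = _single_block_design(onset=20.0, duration=10.0, total=60.0)
        y = np.zeros(d.n_samples) + r.normal(0, sigma, d.n_samples)
        y[d.sample_mask("task")] += delta
        return d, y

    def test_zero_difference_gives_zero_d(self):
        d, y = self._toy(0.0, sigma=0.05)
        cond = d.sample_mask("task")
        base = np.zeros_like(cond)
        base[int(10 * FS):int(20 * FS)] = True
        # force exactly equal means
        y[cond] -= y[cond].mean() - y[base].mean()
        out = block_effect_size(_hb(y), d, "task")
        assert abs(out[0]) < 1e-9

    def test_matches_hand_computed_pooled_oracle(self):
        d = _single_block_design(onset=5.0, duration=2.5, total=10.0)
        r = np.random.default_rng(7)
        y = np.zeros(d.n_samples)
        cond = d.sample_mask("task")
        base = np.zeros_like(cond)
        base[int((5.0 - 10.0) * FS):int(5.0 * FS)] = True
        base[:int(5.0 * FS)] = True
        y[cond] = 1.0 + r.normal(0, 0.05, cond.sum())
        y[~cond] = r.normal(0, 0.05, (~cond).sum())
        out = block_effect_size(_hb(y), d, "task", baseline_window_s=10.0)
        c, b = y[cond], y[:int(5.0 * FS)]
        n1, n2 = c.size, b.size
        pooled = np.sqrt(((n1 - 1) * c.var(ddof=1) + (n2 - 1) * b.var(ddof=1))
                         / (n1 + n2 - 2))
        oracle = (c.mean() - b.mean()) / pooled
        assert out[0] == pytest.approx(oracle, abs=1e-9)

    def test_sign_positive_for_increased_hbo(self):
        d, y = self._toy(0.5)
        out = block_effect_size(_hb(y), d, "task")
        assert out[0] > 0

    def test_baseline_denominator_switch(self):
        d, y = self._toy(0.5)
        pooled = block_effect_size(_hb(y), d, "task", denominator="pooled")
        base = block_effect_size(_hb(y), d, "task", denominator="baseline")
        assert np.isfinite(pooled[0]) and np.isfinite(base[0])
        assert pooled[0] != base[0]

    def test_empty_baseline_after_masking_gives_nan(self):
        d, y = self._toy(0.5)
        valid = np.ones((1, d.n_samples), bool)
        valid[0, :int(20 * FS)] = False  # kill the prestimulus window
        out = block_effect_size(_hb(y, valid), d, "task")
        assert np.isnan(out[0])


class TestCoactivation:
    def _design(self, n=400):
        return TaskDesign(blocks=[Block("vr", 5.0, 30.0)], sampling_rate=FS,
                          total_duration=n / FS)

    def test_identical_channels_correlate_at_one(self, rng):
        d = self._design()
        x = rng.normal(size=d.n_samples)
        hbo = np.vstack([x] * 8)
        fc, pairs = coactivation_matrix(_hb(hbo), d, "vr")
        assert np.allclose(fc, 1.0)

    def test_negated_channel_correlates_at_minus_one(self, rng):
        d = self._design()
        x = rng.normal(size=d.n_samples)
        hbo = np.vstack([x, -x] + [rng.normal(size=d.n_samples)] * 6)
        fc, _ = coactivation_matrix(_hb(hbo), d, "vr")
        assert fc[0, 1] == pytest.approx(-1.0)

    def test_symmetric_unit_diagonal_bounded(self, rng):
        d = self._design()
        hbo = rng.normal(size=(8, d.n_samples))
        fc, pairs = coactivation_matrix(_hb(hbo), d, "vr")
        assert np.allclose(fc, fc.T, equal_nan=True)
        assert np.allclose(np.diag(fc), 1.0)
        assert np.nanmax(np.abs(fc)) <= 1.0 + 1e-12

    def test_pairs_vector_consistent_with_matrix(self, rng):
        d = self._design()
        hbo = rng.normal(size=(8, d.n_samples))
        fc, pairs = coactivation_matrix(_hb(hbo), d, "vr")
        for k, (i, j) in enumerate(FC_PAIRS):
            assert pairs[k] == fc[i - 1, j - 1]

    def test_constant_channel_yields_missing_r(self, rng):
        d = self._design()
        hbo = rng.normal(size=(8, d.n_samples))
        hbo[2] = 1.0
        fc, _ = coactivation_matrix(_hb(hbo), d, "vr")
        assert np.isnan(fc[2, [0, 1, 3, 4, 5, 6, 7]]).all()

    def test_pearson_matches_direct_formula(self, rng):
        d = self._design()
        hbo = rng.normal(size=(8, d.n_samples))
        fc, _ = coactivation_matrix(_hb(hbo), d, "vr")
        m = d.sample_mask("vr")
        x, y = hbo[0, m], hbo[4, m]
        oracle = (((x - x.mean()) * (y - y.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum()
                            * ((y - y.mean()) ** 2).sum()))
        assert fc[0, 4] == pytest.approx(oracle, abs=1e-12)


class TestPairEnumerationAndRegions:
    # the five anatomical pair identities used in reporting
    @pytest.mark.parametrize("k, pair, label", [
        (3, (1, 4), "right-lateral_right-medial"),
        (4, (1, 5), "right-lateral_left-medial"),
        (18, (3, 8), "right-medial_left-lateral"),
        (21, (4, 7), "right-medial_left-lateral"),
        (23, (5, 6), "within_left-medial"),
    ])
    def test_fc_indices_map_to_reported_region_labels(self, k, pair, label):
        assert FC_PAIRS[k - 1] == pair
        assert fc_index(*pair) == k
        assert fc_pair_region_label(k) == label

    def test_region_map_constraints(self):
        assert DEFAULT_REGION_MAP[4] == "right-medial"
        assert DEFAULT_REGION_MAP[8] == "left-lateral"
        from collections import Counter

        assert all(v == 2 for v in Counter(DEFAULT_REGION_MAP.values()).values())

    def test_constant_fc_gives_constant_region_averages(self):
        fc = np.full((8, 8), 0.5)
        np.fill_diagonal(fc, 1.0)
        out = region_pair_fc(fc)
        for (ra, rb), v in out.items():
            assert v == pytest.approx(0.5)

    def test_region_average_matches_hand_mean(self, rng):
        fc = rng.uniform(-1, 1, (8, 8))
        fc = (fc + fc.T) / 2
        np.fill_diagonal(fc, 1.0)
        out = region_pair_fc(fc)
        # right-lateral = ch 1,2; left-medial = ch 5,6
        hand = np.mean([fc[0, 4], fc[0, 5], fc[1, 4], fc[1, 5]])
        assert out[("right-lateral", "left-medial")] == pytest.approx(hand)
        assert out[("left-medial", "left-medial")] == pytest.approx(fc[4, 5])

    def test_permuting_channels_within_region_preserves_region_fc(self, rng):
        fc = rng.uniform(-1, 1, (8, 8))
        fc = (fc + fc.T) / 2
        np.fill_diagonal(fc, 1.0)
        # swap channels 5 and 6 (both left-medial)
        perm = [0, 1, 2, 3, 5, 4, 6, 7]
        fc_perm = fc[np.ix_(perm, perm)]
        a, b = region_pair_fc(fc), region_pair_fc(fc_perm)
        for key in a:
            assert a[key] == pytest.approx(b[key])


class TestEndToEndSubjectMetrics:
    def test_beta_and_d_sign_agree_on_noiseless_data(self, short_design,
                                                     quiet_recording):
        from vrnirs.preprocess import run_preprocessing

        hb, _ = run_preprocessing(quiet_recording)
        m = compute_subject_metrics(hb, short_design,
                                    filter_params=FilterParams())
        pos = m.beta > 0.01
        assert np.all(np.sign(m.cohen_d[pos]) == 1.0)
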