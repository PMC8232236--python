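"""Synthetic cohort generator: determinism, calibration, ground-truth
structure and SIAS coupling."""

import numpy as np
import pytest
from scipy import stats

from dmnpdc.mvar import check_stability
from dmnpdc.pdc import DEFAULT_BANDS
from dmnpdc.synthetic import (
    ALPHA_TARGETS,
    GROUPS,
    SIAS_BINS,
    analytic_band_pdc,
    load_cohort,
    make_cohort,
    make_group_spec,
    mean_offdiag,
    save_cohort,
    simulate_recording,
    simulate_sias,
)

ALPHA_K = DEFAULT_BANDS.names.index("alpha")
DELTA_K = DEFAULT_BANDS.names.index("delta")


class TestGroupSpec:
    def test_seeded_determinism(self):
        a = make_group_spec("control", 7)
        b = make_group_spec("control", 7)
        assert a.coupling_edges == b.coupling_edges

    @pytest.mark.parametrize("group", GROUPS)
    def test_specs_are_stable(self, group):
        for seed in (0, 1, 2):
            spec = make_group_spec(group, seed)
            assert check_stability(spec.to_model())

    @pytest.mark.parametrize("group", ["severe", "moderate"])
    def test_precuneus_is_dominant_hub(self, group):
        spec = make_group_spec(group, 1)
        deg = spec.out_degree()
        assert deg["PZ"] >= max(v for k, v in deg.items() if k != "PZ")

    def test_control_has_elevated_frontal_outflow(self):
        deg = make_group_spec("control", 3).out_degree()
        frontal = deg["FZ"] + deg["F3"] + deg["F4"]
        posterior = deg["PZ"] + deg["P3"] + deg["P4"]
        assert frontal > posterior

    def test_zero_coupling_gives_exactly_zero_offdiag_pdc(self):
        spec = make_group_spec("mild", 5, coupling_scale=0.0)
        bam = analytic_band_pdc(spec)
        off = ~np.eye(8, dtype=bool)
        assert np.all(bam[off] == 0.0)

    @pytest.mark.parametrize("group", GROUPS)
    def test_alpha_band_calibration_within_30_percent(self, group):
        for seed in range(5):
            spec = make_group_spec(group, seed)
            alpha = mean_offdiag(analytic_band_pdc(spec)[:, :, ALPHA_K])
            assert 0.7 * ALPHA_TARGETS[group] <= alpha <= 1.3 * ALPHA_TARGETS[group]

    def test_delta_ordering_of_group_templates(self):
        means = {
            g: np.mean(
                [
                    mean_offdiag(
                        analytic_band_pdc(make_group_spec(g, s))[:, :, DELTA_K]
                    )
                    for s in range(5)
                ]
            )
            for g in GROUPS
        }
        assert min(means["mild"], means["moderate"]) > 2 * max(
            means["control"], means["severe"]
        )

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            make_group_spec("extreme", 0)


class TestSimulateRecording:
    def test_shape_and_determinism(self):
        spec = make_group_spec("control", 1)
        a = simulate_recording(spec, duration_s=10.0, fs=256, seed=9)
        b = simulate_recording(spec, duration_s=10.0, fs=256, seed=9)
        assert a.data.shape == (8, 2560)
        assert np.array_equal(a.data, b.data)
        assert a.labels == spec.montage.labels

    def test_raw_rate_sample_count(self):
        spec = make_group_spec("control", 1)
        rec = simulate_recording(spec, duration_s=10.0, fs=2048, seed=1)
        assert rec.data.shape == (8, 20480)
        assert rec.fs == 2048.0

    def test_uncoupled_channels_are_uncorrelated(self):
        spec = make_group_spec("severe", 2, coupling_scale=0.0)
        rec = simulate_recording(spec, duration_s=120.0, fs=256, seed=3)
        x = rec.data - rec.data.mean(axis=1, keepdims=True)
        x /= x.std(axis=1, keepdims=True)
        n = x.shape[1]
        for lag in (0, 1, 4):
            for i, j in [(0, 3), (2, 5), (1, 7)]:
                r = (x[i, : n - lag] * x[j, lag:]).mean()
                assert abs(r) < 0.05

    def test_single_edge_has_directional_lagged_correlation(self):
        # a spec with a single lag-1 edge CP5 -> PZ (strength 0.4): the
        # forward lagged cross-correlation exceeds the reverse at every lag
        from dmnpdc.synthetic import GroundTruthSpec, _ORDER

        spec = GroundTruthSpec(
            group="mild",
            order=_ORDER,
            coupling_edges=(("CP5", "PZ", 0.4),),
            noise_cov=np.eye(8),
        )
        rec = simulate_recording(spec, duration_s=120.0, fs=256, seed=5)
        i_s = spec.montage.index("CP5")
        i_t = spec.montage.index("PZ")
        x = rec.data - rec.data.mean(axis=1, keepdims=True)
        x /= x.std(axis=1, keepdims=True)
        n = x.shape[1]
        for lag in (1, 2, 5):
            fwd = (x[i_s, : n - lag] * x[i_t, lag:]).mean()
            rev = (x[i_t, : n - lag] * x[i_s, lag:]).mean()
            assert abs(fwd) > abs(rev)

    def test_line_noise_peak_present_when_enabled(self):
        from scipy import signal as sps

        spec = make_group_spec("control", 1, line_noise=20.0)
        rec = simulate_recording(spec, duration_s=30.0, fs=256, seed=2)
        f, p = sps.welch(rec.data[0], fs=256.0, nperseg=1024)
        peak = p[np.argmin(np.abs(f - 50.0))]
        neighbours = p[np.argmin(np.abs(f - 45.0))]
        assert peak > 50 * neighbours

    def test_precondition_errors(self):
        spec = make_group_spec("control", 1)
        with pytest.raises(ValueError):
            simulate_recording(spec, duration_s=4.0)
        with pytest.raises(ValueError):
            simulate_recording(spec, duration_s=10.0, fs=512)
        with pytest.raises(ValueError):
            simulate_recording(spec, duration_s=10.0, burn_in_s=0.01)


class TestSias:
    @pytest.mark.parametrize("group", GROUPS)
    def test_scores_respect_group_bins(self, group):
        lo, hi = SIAS_BINS[group]
        _, ref = __import__(
            "dmnpdc.synthetic", fromlist=["_calibrated_template"]
        )._calibrated_template(group)
        for seed in range(30):
            s = simulate_sias(group, ref * (0.8 + 0.02 * seed), seed)
            assert lo <= s <= hi

    def test_severe_positive_control_negative_coupling(self):
        rng = np.random.default_rng(0)
        for group, sign in (("severe", 1), ("control", -1)):
            from dmnpdc.synthetic import _calibrated_template

            _, ref = _calibrated_template(group)
            pdc = ref * (1 + 0.08 * rng.standard_normal(22))
            scores = [simulate_sias(group, float(p), s) for s, p in enumerate(pdc)]
            r, p = stats.pearsonr(pdc, scores)
            assert sign * r > 0 and p < 0.05

    def test_zero_coupling_gives_null_correlations(self):
        # rejection rate of the correlation test at alpha=0.05 stays within
        # binomial bounds over 200 seeded draws of 22 subjects
        from dmnpdc.synthetic import _calibrated_template

        _, ref = _calibrated_template("severe")
        rng = np.random.default_rng(1)
        rejections = 0
        for rep in range(200):
            pdc = ref * (1 + 0.08 * rng.standard_normal(22))
            scores = [
                simulate_sias("severe", float(p), 1000 * rep + k, coupling=0.0)
                for k, p in enumerate(pdc)
            ]
            _, p = stats.pearsonr(pdc, scores)
            rejections += p < 0.05
        assert rejections < 0.05 * 200 + 3 * np.sqrt(200 * 0.05 * 0.95)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_sias("nope", 0.05, 0)
        with pytest.raises(ValueError):
            simulate_sias("severe", 1.5, 0)


class TestCohort:
    def test_counts_and_determinism(self):
        a = make_cohort(n_per_group=3, duration_s=10.0, seed=0)
        b = make_cohort(n_per_group=3, duration_s=10.0, seed=0)
        assert len(a.subjects) == 12
        for sa, sb in zip(a.subjects, b.subjects):
            assert sa.sias == sb.sias
            assert np.array_equal(sa.recording.data, sb.recording.data)

    def test_enlarging_cohort_keeps_existing_subjects(self):
        small = make_cohort(n_per_group=3, duration_s=10.0, seed=4)
        large = make_cohort(n_per_group=4, duration_s=10.0, seed=4)
        by_id = {s.id: s for s in large.subjects}
        for s in small.subjects:
            assert np.array_equal(s.recording.data, by_id[s.id].recording.data)

    def test_group_sizes(self, small_cohort):
        for g in GROUPS:
            assert len(small_cohort.group_subjects(g)) == 4

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(n_per_group=2, duration_s=10.0)

    def test_save_load_roundtrip(self, tmp_path):
        cohort = make_cohort(n_per_group=3, duration_s=10.0, seed=2)
        save_cohort(cohort, tmp_path)
        back = load_cohort(tmp_path)
        assert len(back.subjects) == 12
        for a, b in zip(cohort.subjects, back.subjects):
            assert a.id == b.id and a.sias == b.sias
            assert np.allclose(a.recording.data, b.recording.data, atol=1e-4)


def test_estimated_pdc_converges_to_analytic_oracle():
    """Band-averaged PDC estimated from simulated epochs approaches the
    analytic PDC of the generating model, improving with duration."""
    from dmnpdc.pdc import subject_connectivity

    spec = make_group_spec("mild", 3)
    truth = analytic_band_pdc(spec)
    off = ~np.eye(8, dtype=bool)
    maes = []
    for dur in (32, 116):
        rec = simulate_recording(spec, duration_s=float(dur), fs=256, seed=8)
        n_ep = int(dur // 4)
        epochs = rec.data.reshape(8, n_ep, 1024).transpose(1, 0, 2)

        class E:
            pass

        e = E()
        e.epochs, e.fs, e.labels = epochs, 256.0, ()
        t = subject_connectivity(e, order_policy=6)
        maes.append(np.abs(t.values[off] - truth[off]).mean())
    assert maes[1] < 0.05
    assert maes[1] < maes[0]
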