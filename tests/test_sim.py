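"""Exit-block simulator: waveform, interval equation, block
probability, conservation, presets, cohort generation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exitblock.core import CLASS_ORDER, Diagnosis
from exitblock.metrics import basic_metrics
from exitblock.sim import (
    DEFAULT_COHORT_START_MS,
    SimParams,
    block_probability,
    generate_labeled_cohort,
    next_internal_interval,
    preset,
    preset_for,
    simulate,
    vagal_tone,
)


class _ForcedRng:
    """Stand-in generator returning a fixed uniform draw."""

    def __init__(self, value: float) -> None:
        self.value = value

    def random(self) -> float:
        return self.value


def _flat_params(level: float, **kwargs) -> SimParams:
    """Parameters with a constant vagal tone equal to ``level``."""
    base = dict(t0=200.0, tb=200.0, ebpsf=0.7, vagal_offset=level, resp_amp=0.0, circ_amp=0.0)
    base.update(kwargs)
    return SimParams(**base)


class TestVagalTone:
    def test_offset_only(self):
        p = _flat_params(0.08)
        assert vagal_tone(12345.0, p) == pytest.approx(0.08)

    def test_respiratory_period_4000ms(self):
        p = SimParams(t0=200, tb=200, ebpsf=0.7, circ_amp=0.0)
        t = np.linspace(0, 20000, 500)
        np.testing.assert_allclose(vagal_tone(t, p), vagal_tone(t + 4000.0, p), atol=1e-12)

    def test_default_waveform_bounded_over_24h(self):
        p = preset("normal")
        t = np.linspace(0, 86.4e6, 200001)
        vt = vagal_tone(t, p)
        assert vt.min() > 0.0
        assert vt.max() < 1.2

    def test_circadian_peak_is_mid_recording(self):
        p = preset("normal")
        assert vagal_tone(43.2e6, p) > vagal_tone(0.0, p)


class TestInternalInterval:
    def test_formula_with_zero_noise(self):
        p = _flat_params(0.5)
        assert next_internal_interval(0.0, False, p, _ForcedRng(0.0)) == pytest.approx(400.0)

    def test_post_block_noise_span_uses_tb(self):
        snd = dataclasses.replace(preset("snd"), vagal_offset=0.5, resp_amp=0.0, circ_amp=0.0)
        after_block = next_internal_interval(0.0, True, snd, _ForcedRng(1.0 - 1e-12))
        after_conducted = next_internal_interval(0.0, False, snd, _ForcedRng(1.0 - 1e-12))
        assert after_block == pytest.approx(400.0 + 50.0, abs=1e-6)
        assert after_conducted == pytest.approx(400.0 + 40.0, abs=1e-6)

    def test_monte_carlo_matches_uniform_mean(self):
        p = _flat_params(0.5)
        rng = np.random.default_rng(0)
        draws = np.array([next_internal_interval(0.0, False, p, rng) for _ in range(10_000)])
        assert draws.min() >= 400.0
        assert draws.max() < 440.0
        assert draws.mean() == pytest.approx(420.0, abs=1.0)


class TestBlockProbability:
    @pytest.mark.parametrize(
        "vt,ebpsf,expected",
        [(0.5, 1.8, 0.0), (0.8, 1.8, 0.36), (0.8, 0.7, 0.14)],
    )
    def test_threshold_and_slope(self, vt, ebpsf, expected):
        p = SimParams(t0=200, tb=200, ebpsf=ebpsf)
        assert block_probability(vt, p) == pytest.approx(expected)

    def test_clamped_at_one(self):
        p = SimParams(t0=200, tb=200, ebpsf=10.0)
        assert block_probability(0.9, p) == 1.0

    @settings(max_examples=50, deadline=None)
    @given(
        st.floats(min_value=0.0, max_value=1.2),
        st.floats(min_value=0.0, max_value=1.2),
        st.floats(min_value=0.0, max_value=3.0),
        st.floats(min_value=0.0, max_value=3.0),
    )
    def test_monotone_in_tone_and_slope(self, vt1, vt2, e1, e2):
        lo_vt, hi_vt = sorted((vt1, vt2))
        lo_e, hi_e = sorted((e1, e2))
        p_lo = SimParams(t0=200, tb=200, ebpsf=lo_e)
        p_hi = SimParams(t0=200, tb=200, ebpsf=hi_e)
        assert block_probability(lo_vt, p_lo) <= block_probability(hi_vt, p_lo)
        assert block_probability(hi_vt, p_lo) <= block_probability(hi_vt, p_hi)


class TestSimulate:
    def test_no_block_limit(self):
        p = _flat_params(0.8, ebpsf=0.0)
        r = simulate(p, 600_000.0, seed=1)
        assert r.n_blocked == 0
        np.testing.assert_array_equal(r.series.intervals, r.internal_intervals)

    def test_conducted_time_conservation(self):
        r = simulate(preset("snd"), 3.6e6, seed=2, start_time_ms=DEFAULT_COHORT_START_MS)
        assert r.n_blocked > 0
        conducted_idx = np.flatnonzero(~r.blocked)
        last = conducted_idx[-1]
        assert r.series.intervals.sum() == pytest.approx(r.internal_intervals[: last + 1].sum())

    def test_conducted_rr_sums_internal_intervals(self):
        r = simulate(preset("snd"), 600_000.0, seed=3, start_time_ms=DEFAULT_COHORT_START_MS)
        # rebuild conducted intervals from the internal beat log
        rebuilt, acc = [], 0.0
        for tint, blocked in zip(r.internal_intervals, r.blocked):
            acc += tint
            if not blocked:
                rebuilt.append(acc)
                acc = 0.0
        np.testing.assert_allclose(r.series.intervals, rebuilt)

    def test_threshold_above_tone_degenerates_to_sinus_rhythm(self):
        p = dataclasses.replace(preset("snd"), vth=2.0)
        r = simulate(p, 3.6e6, seed=4, start_time_ms=DEFAULT_COHORT_START_MS)
        assert r.n_blocked == 0

    def test_snd_intervals_cluster_near_integer_multiples(self):
        """Conducted intervals spanning blocked beats land near integer
        multiples of the local internal cycle."""
        r = simulate(preset("snd"), 3.6e6, seed=5, start_time_ms=DEFAULT_COHORT_START_MS)
        base = np.median(r.internal_intervals)
        multi = r.series.intervals[r.series.intervals > 1.5 * base]
        assert multi.size > 50
        ratios = multi / base
        assert np.median(np.abs(ratios - np.round(ratios))) < 0.25

    def test_snd_has_more_long_pauses_than_normal(self):
        kw = dict(duration_ms=3.6e6, start_time_ms=DEFAULT_COHORT_START_MS)
        pauses = {
            name: basic_metrics(simulate(preset(name), seed=6, **kw).series).n_pauses_gt2
            for name in ("normal", "snd")
        }
        assert pauses["snd"] > pauses["normal"]

    def test_reproducible_per_seed(self):
        a = simulate(preset("hplsm"), 600_000.0, seed=7)
        b = simulate(preset("hplsm"), 600_000.0, seed=7)
        np.testing.assert_array_equal(a.series.intervals, b.series.intervals)


class TestPresets:
    def test_published_parameter_sets(self):
        normal, hplsm, snd = preset("normal"), preset("hplsm"), preset("snd")
        assert (normal.t0, normal.tb, normal.ebpsf) == (200.0, 200.0, 0.7)
        assert hplsm.t0 == 500.0
        assert (hplsm.tb, hplsm.ebpsf) == (200.0, 0.7)  # inherited from normal
        assert (snd.t0, snd.tb, snd.ebpsf) == (200.0, 50.0, 1.8)
        for p in (normal, hplsm, snd):
            assert p.vtdps == 400.0 and p.vth == 0.6

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            preset("cat")

    def test_preset_for_diagnosis(self):
        assert preset_for(Diagnosis.SND).ebpsf == 1.8


class TestCohort:
    def test_counts_and_labels(self):
        cohort = generate_labeled_cohort(3, 600_000.0, seed=0)
        assert len(cohort) == 9
        for d in CLASS_ORDER:
            assert sum(1 for _, label in cohort if label is d) == 3

    def test_deterministic_for_master_seed(self):
        a = generate_labeled_cohort(2, 300_000.0, seed=9)
        b = generate_labeled_cohort(2, 300_000.0, seed=9)
        for (sa, _), (sb, _) in zip(a, b):
            np.testing.assert_array_equal(sa.intervals, sb.intervals)

    def test_recordings_differ_across_children(self):
        cohort = generate_labeled_cohort(2, 300_000.0, seed=9)
        assert not np.array_equal(cohort[0][0].intervals, cohort[1][0].intervals)
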