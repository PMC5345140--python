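import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryptmeth.dmep_caller import (
    DmepParams,
    assemble_peaks,
    call_dmeps,
    m_prime,
    probe_cv,
    summarize_dmeps,
)

from conftest import make_probe_table, random_probe_table
from oracles import brute_force_dmep_calls


class TestAssemblePeaks:
    def test_runs_enumerated_by_hand(self):
        table = make_probe_table(pooled_means=[0.5, 0.6, -0.1, 0.7])
        params = DmepParams(probe_call_threshold=0.2, min_probes_per_peak=2)
        peaks = assemble_peaks(table, params)
        assert len(peaks) == 1
        assert peaks[0].probe_ids == ["P1", "P2"]

    def test_all_below_threshold_yields_nothing(self):
        table = make_probe_table(pooled_means=[0.0, 0.1, -0.5])
        assert assemble_peaks(table, DmepParams(probe_call_threshold=0.2)) == []

    def test_min_one_probe_gives_maximal_runs(self):
        table = make_probe_table(pooled_means=[0.5, 0.6, 0.7])
        peaks = assemble_peaks(table, DmepParams(min_probes_per_peak=1))
        assert len(peaks) == 1
        assert peaks[0].n_probes == 3

    def test_peaks_never_cross_promoter_boundaries(self):
        table = make_probe_table(
            pooled_means=[0.5, 0.6, 0.5, 0.6],
            promoter_ids=["promA", "promA", "promB", "promB"],
        )
        peaks = assemble_peaks(table, DmepParams())
        assert [p.promoter_id for p in peaks] == ["promA", "promB"]


class TestMPrime:
    def test_identical_groups_gives_zero(self):
        table = make_probe_table(pooled_means=[0.5, 0.7])
        (peak,) = assemble_peaks(table, DmepParams())
        assert m_prime(peak, table) == 0.0

    def test_closed_form_difference(self):
        values = [[0.25, 0.25, 0.25, 1.0, 1.0, 1.0]] * 3
        table = make_probe_table(per_probe_values=values)
        (peak,) = assemble_peaks(table, DmepParams())
        assert m_prime(peak, table) == pytest.approx(0.75)

    def test_matches_double_mean_on_random_block(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0.5, 0.3, size=(3, 6)).tolist()
        table = make_probe_table(per_probe_values=values)
        (peak,) = assemble_peaks(table, DmepParams(probe_call_threshold=-10))
        case = table.values(table.groups["case"])
        control = table.values(table.groups["control"])
        expected = case.mean() - control.mean()
        assert m_prime(peak, table) == pytest.approx(expected, rel=1e-12)


class TestProbeCV:
    @pytest.mark.parametrize(
        "reps,expected",
        [((1.0, 1.0, 1.0), 0.0), ((1.0, 2.0, 3.0), 0.5)],
    )
    def test_closed_forms(self, reps, expected):
        values = [list(reps) + [0.0] * 3]
        table = make_probe_table(per_probe_values=values)
        assert probe_cv(table, "P1", "control") == pytest.approx(expected)

    def test_zero_mean_gives_infinity(self):
        values = [[-1.0, 1.0, 0.0, 0.0]]
        table = make_probe_table(per_probe_values=values, n_control=2, n_case=2)
        assert probe_cv(table, "P1", "control") == math.inf

    def test_single_replicate_rejected(self):
        values = [[0.5, 0.5, 0.5, 0.5]]
        table = make_probe_table(per_probe_values=values, n_control=1, n_case=3)
        with pytest.raises(ValueError):
            probe_cv(table, "P1", "control")


class TestCallDmeps:
    def _call_single(self, per_probe_values, **params):
        table = make_probe_table(per_probe_values=per_probe_values)
        p = DmepParams(**params)
        return call_dmeps(assemble_peaks(table, p), table, p), table

    def test_control_higher_example(self):
        # control median 0.35, case median 0.10 -> M' = -0.25, tight CVs
        values = [[0.35, 0.36, 0.34, 0.10, 0.11, 0.09]] * 3
        called, _ = self._call_single(values, probe_call_threshold=0.1)
        assert called[0].dmep_class == "control_higher"
        assert called[0].m_prime < 0

    def test_below_enrichment_threshold_is_none(self):
        values = [[0.21, 0.20, 0.19, 0.20, 0.21, 0.19]] * 3
        called, _ = self._call_single(values, probe_call_threshold=0.1)
        assert called[0].enrichment_pass is False
        assert called[0].dmep_class == "none"

    def test_cv_fraction_below_half_is_none(self):
        # 1 of 4 probes has a tight control CV; the rest straddle zero mean
        good = [0.50, 0.52, 0.48]
        noisy = [0.40, -0.35, 0.02]
        values = [
            good + good,
            noisy + good,
            noisy + good,
            noisy + good,
        ]
        called, _ = self._call_single(values, probe_call_threshold=0.0)
        (peak,) = called
        assert peak.cv_pass_fraction["control"] == pytest.approx(0.25)
        assert peak.cv_pass is False
        assert peak.dmep_class == "none"

    def test_one_sided_mode_drops_control_higher(self):
        values = [[0.50, 0.51, 0.49, 0.10, 0.11, 0.09]] * 3
        called, _ = self._call_single(values, one_sided=True)
        assert called[0].dmep_class == "none"
        called2, _ = self._call_single(values, one_sided=False)
        assert called2[0].dmep_class == "control_higher"

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(17)
        params = DmepParams()
        table = random_probe_table(rng, n_promoters=40)
        called = call_dmeps(assemble_peaks(table, params), table, params)
        expected = brute_force_dmep_calls(table, params)
        assert len(called) == len(expected)
        for got, want in zip(called, expected):
            assert got.promoter_id == want["promoter_id"]
            assert got.probe_ids == want["probe_ids"]
            assert got.dmep_class == want["dmep_class"]
            assert got.m_prime == pytest.approx(want["m_prime"], rel=1e-9)

    def test_label_swap_negates_m_prime_and_swaps_classes(self):
        rng = np.random.default_rng(23)
        params = DmepParams()
        table = random_probe_table(rng, n_promoters=60)
        called = call_dmeps(assemble_peaks(table, params), table, params)
        swapped = table.swap_groups()
        called_sw = call_dmeps(assemble_peaks(swapped, params), swapped, params)
        assert len(called) == len(called_sw)
        flip = {"case_higher": "control_higher", "control_higher": "case_higher", "none": "none"}
        for a, b in zip(called, called_sw):
            assert b.m_prime == pytest.approx(-a.m_prime, abs=1e-12)
            assert b.dmep_class == flip[a.dmep_class]

    @settings(max_examples=20, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        d_median=st.floats(0.0, 0.3),
        d_cv=st.floats(0.0, 0.5),
    )
    def test_tightening_thresholds_never_increases_count(self, seed, d_median, d_cv):
        rng = np.random.default_rng(seed)
        table = random_probe_table(rng, n_promoters=15)
        loose = DmepParams()
        tight = DmepParams(median_min=loose.median_min + d_median, cv_max=loose.cv_max - d_cv)
        peaks = assemble_peaks(table, loose)
        n_loose = sum(p.dmep_class != "none" for p in call_dmeps(peaks, table, loose))
        n_tight = sum(p.dmep_class != "none" for p in call_dmeps(peaks, table, tight))
        assert n_tight <= n_loose


class TestSummarize:
    def test_empty_input(self, probe_table_factory):
        table = probe_table_factory(pooled_means=[0.0])
        summary = summarize_dmeps([], table)
        assert summary.n_dmep == 0
        assert summary.n_total_methylated == 0
        assert math.isnan(summary.t_p)

    def test_counts_by_class(self):
        values = [[0.9, 0.9, 0.9, 0.2, 0.2, 0.21]] * 2 + [[0.2, 0.2, 0.21, 0.9, 0.9, 0.9]] * 2
        table = make_probe_table(
            per_probe_values=values, promoter_ids=["a", "a", "b", "b"]
        )
        params = DmepParams()
        called = call_dmeps(assemble_peaks(table, params), table, params)
        summary = summarize_dmeps(called, table, params)
        assert (summary.n_control_higher, summary.n_case_higher) == (1, 1)
        assert summary.n_dmep == 2
        assert summary.n_total_methylated == 2
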