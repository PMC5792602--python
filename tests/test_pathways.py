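"""Pathway classification, flux estimates and group comparisons."""

import numpy as np
import pytest

from azmech.pathways import (
    Cascade,
    PathwayRecord,
    bootstrap_flux,
    classify_dataset,
    classify_domain,
    classify_trace,
    compare_delta_lc,
    flux,
    force_correlation,
    group_cascades,
    speed_sweep,
)
from azmech.synthetic import apo_pathways, generate_dataset
from azmech.trace import GeneratorConfig
from azmech.wlc import UnfoldingEvent, WLCFit


def _event(lc, force=50.0, jump=0.5):
    return UnfoldingEvent(
        peak_force=force,
        peak_extension=lc * 0.85,
        fit=WLCFit(Lc=lc, p=0.4, T=298.0, rss=0.0, n_points=50),
        event_index=int(lc * 10),
        ext_jump=jump,
    )


def _cascade(lcs, total, forces=None):
    events = [_event(lc, f) for lc, f in zip(lcs, forces or [50.0] * len(lcs))]
    return Cascade(events=events, lc_values=list(lcs), total_delta_lc=total)


class TestClassifyDomain:
    def test_single_peak_is_two_state(self):
        record = classify_domain(_cascade([50.0], 37.0))
        assert record.n_states == 2
        assert not record.ambiguous

    def test_two_peaks_with_worked_increments_is_three_state(self):
        record = classify_domain(_cascade([50.0, 57.5], 37.2))
        assert record.n_states == 3
        assert record.delta_lcs[0] == pytest.approx(7.5)

    def test_total_outside_tolerance_flagged_ambiguous(self):
        record = classify_domain(_cascade([50.0], 60.0), lc_tolerance=10.0)
        assert record.ambiguous

    @pytest.mark.parametrize("n_peaks,expected", [(1, 2), (2, 3), (3, 4)])
    def test_state_count_matches_rule_evaluator(self, n_peaks, expected):
        """Brute-force rule: n_states = resolved rupture peaks + 1."""
        lcs = [50.0 + 6.0 * k for k in range(n_peaks)]
        record = classify_domain(_cascade(lcs, 37.0))
        assert record.n_states == expected

    def test_force_rescaling_leaves_class_unchanged(self):
        base = classify_domain(_cascade([50.0, 57.5], 37.2, forces=[56.0, 46.0]))
        scaled = classify_domain(_cascade([50.0, 57.5], 37.2, forces=[112.0, 92.0]))
        assert base.n_states == scaled.n_states


class TestGroupCascades:
    def test_grouping_splits_on_large_increment(self):
        events = [_event(50.0), _event(57.5), _event(87.2), _event(124.4)]
        cascades = group_cascades(events)
        assert [c.n_peaks for c in cascades] == [2, 1, 1]
        assert cascades[-1].is_terminal
        assert cascades[0].total_delta_lc == pytest.approx(37.2)

    def test_empty_events_give_no_cascades(self):
        assert group_cascades([]) == []


class TestFlux:
    def test_all_three_state(self):
        records = [PathwayRecord(0, i, 3, (7.5, 37.0), (56.0, 46.0)) for i in range(5)]
        estimate = flux(records)
        assert estimate.fraction == {3: 100.0}

    def test_fractions_sum_to_100(self, apo_traces):
        records = classify_dataset(apo_traces)
        estimate = flux(records)
        assert sum(estimate.fraction.values()) == pytest.approx(100.0)

    def test_empty_dataset_is_an_error(self):
        with pytest.raises(ValueError, match="no unambiguous"):
            flux([])


class TestBootstrapFlux:
    def test_homogeneous_dataset_has_zero_se(self):
        records = [PathwayRecord(i, 0, 2, (37.0,), (56.0,)) for i in range(20)]
        estimate = bootstrap_flux(records, n_resamples=100, seed=0)
        assert estimate.se[2] == 0.0

    def test_se_matches_binomial_for_single_domain_traces(self):
        """Trace-level resampling of single-domain traces is binomial."""
        cfg = GeneratorConfig(seed=2, noise_sd=5.0, n_domains=1)
        traces = generate_dataset(cfg, apo_pathways(three_state_weight=0.5), 200, seed=77)
        records = classify_dataset(traces)
        estimate = bootstrap_flux(records, n_resamples=500, seed=9)
        binomial = 100.0 * np.sqrt(0.25 / estimate.n_traces)
        assert estimate.se[3] == pytest.approx(binomial, rel=0.2)

    def test_fixed_seed_reproducible(self, apo_traces):
        records = classify_dataset(apo_traces)
        a = bootstrap_flux(records, n_resamples=100, seed=4)
        b = bootstrap_flux(records, n_resamples=100, seed=4)
        assert a.se == b.se


class TestForceCorrelation:
    def test_weaker_intermediate_dominates_pairs(self, apo_traces):
        records = classify_dataset(apo_traces)
        pairs, fraction = force_correlation(records)
        assert pairs.shape[1] == 2
        assert fraction > 0.5

    def test_identical_forces_give_zero_fraction(self):
        records = [PathwayRecord(0, 0, 3, (7.5, 37.0), (50.0, 50.0))]
        _, fraction = force_correlation(records)
        assert fraction == 0.0

    def test_no_intermediates_is_an_error(self):
        records = [PathwayRecord(0, 0, 2, (37.0,), (56.0,))]
        with pytest.raises(ValueError, match="intermediate"):
            force_correlation(records)


class TestCompareDeltaLc:
    def test_identical_groups_give_p_near_one(self):
        rng = np.random.default_rng(0)
        group = rng.normal(7.5, 1.0, 40)
        p = compare_delta_lc(group, group, n_perm=999, seed=1)
        assert p > 0.9

    def test_widely_separated_groups_hit_the_floor(self):
        rng = np.random.default_rng(0)
        a = rng.normal(7.5, 0.1, 50)
        b = rng.normal(6.5, 0.1, 50)  # 10 SD apart
        p = compare_delta_lc(a, b, n_perm=999, seed=1)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(7.5, 1.5, 30), rng.normal(6.7, 1.2, 30)
        assert compare_delta_lc(a, b, 2000, seed=5) == compare_delta_lc(a, b, 2000, seed=5)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            compare_delta_lc([], [1.0])


class TestSpeedSweep:
    def test_flux_reported_per_speed(self, apo_traces):
        records = classify_dataset(apo_traces)
        table = speed_sweep({400.0: records, 40.0: records}, n_resamples=50, seed=0)
        assert set(table) == {40.0, 400.0}
        assert all(isinstance(v.fraction, dict) for v in table.values())

    def test_missing_key_is_an_error(self):
        with pytest.raises(ValueError, match="no datasets"):
            speed_sweep({})
        with pytest.raises(ValueError, match="pulling speed"):
            speed_sweep({400.0: []})


class TestEndToEndRecovery:
    def test_mixture_recovered_within_three_binomial_sd(self, apo_traces_100):
        records = classify_dataset(apo_traces_100)
        estimate = flux(records)
        labels = np.asarray([n for t in apo_traces_100 for n in t.pathway_labels])
        truth = 100.0 * np.mean(labels == 3)
        sd = 100.0 * np.sqrt(truth / 100 * (1 - truth / 100) / labels.size)
        assert abs(estimate.fraction[3] - truth) < 3 * sd
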