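"""Cohort generator: determinism, invariants, and distributional recovery."""

import numpy as np
import pytest

from conngraph import (
    CohortSpec,
    SubjectRecord,
    framewise_displacement,
    generate_cohort,
    generate_functional_cohort,
    generate_motion_trace,
    generate_structural_cohort,
    generate_symptom_scores,
)
from conngraph.synthetic import AHRS_MEAN, modular_correlation


def test_cohort_is_deterministic_given_seed(tiny_spec):
    a = generate_cohort(tiny_spec)
    b = generate_cohort(tiny_spec)
    for ra, rb in zip(a, b):
        assert ra.subject_id == rb.subject_id
        assert np.array_equal(ra.timeseries.values, rb.timeseries.values)
        assert np.array_equal(ra.motion.translations, rb.motion.translations)
        assert np.array_equal(ra.fiber_counts, rb.fiber_counts)
        assert ra.ahrs_total == rb.ahrs_total


def test_group_sizes_and_symptom_scores_follow_manifest(tiny_spec):
    records = generate_cohort(tiny_spec)
    groups = [r.group_label for r in records]
    assert groups.count("AVH") == 3 and groups.count("nAVH") == 3
    for r in records:
        assert (r.ahrs_total is not None) == (r.group_label == "AVH")
        if r.ahrs_total is not None:
            assert r.ahrs_total >= 0


def test_record_rejects_inconsistent_symptom_score():
    with pytest.raises(ValueError):
        SubjectRecord("x", "HC", ahrs_total=12.0)
    with pytest.raises(ValueError):
        SubjectRecord("x", "AVH")


@pytest.mark.parametrize(
    "kwargs",
    [
        {"rho_within": {"AVH": 0.1, "nAVH": 0.3, "HC": 0.3}, "rho_between": 0.2},
        {"group_sizes": (1, 5, 5)},
        {"n_rois": 91},
        {"fn_mean_within": -1.0},
        {"fn_dispersion": 0.0},
        {"spike_rate": 1.0},
    ],
)
def test_invalid_specs_rejected(kwargs):
    with pytest.raises(ValueError):
        CohortSpec(**kwargs)


def test_non_positive_definite_structure_rejected():
    with pytest.raises(ValueError, match="positive definite"):
        modular_correlation(12, 2, rho_within=0.1, rho_between=0.9)


def test_uncorrelated_spec_gives_null_level_correlations():
    """rho_within = rho_between = 0: empirical |r| sits at the sampling-noise
    level determined by the series length."""
    spec = CohortSpec(
        group_sizes=(17, 17, 16),
        rho_within={"AVH": 0.0, "nAVH": 0.0, "HC": 0.0},
        rho_between=0.0,
        rho_homotopic=0.0,
        nuisance_coupling=0.0,
        spike_rate=0.0,
        seed=9,
    )
    records = generate_functional_cohort(spec)
    per_subject = []
    for rec in records:
        r = np.corrcoef(rec.timeseries.values)
        off = np.abs(r[np.triu_indices_from(r, k=1)])
        per_subject.append(off.mean())
    # E|r| for independent normal series of length T: sqrt(2/(pi*(T-1)))
    expected = np.sqrt(2.0 / (np.pi * (spec.n_volumes - 1)))
    sem = np.std(per_subject, ddof=1) / np.sqrt(len(per_subject))
    assert abs(np.mean(per_subject) - expected) < 3 * sem


def test_within_module_correlation_recovered_at_large_t():
    spec = CohortSpec(
        group_sizes=(2, 2, 2),
        n_volumes=2000,
        rho_within={"AVH": 0.5, "nAVH": 0.5, "HC": 0.5},
        rho_between=0.1,
        rho_homotopic=0.0,
        nuisance_coupling=0.0,
        spike_rate=0.0,
        seed=3,
    )
    records = generate_functional_cohort(spec)
    modules = spec.module_labels
    same = modules[:, None] == modules[None, :]
    iu = np.triu_indices(spec.n_rois, k=1)
    within_vals, between_vals = [], []
    for rec in records:
        r = np.corrcoef(rec.timeseries.values)[iu]
        within_vals.append(r[same[iu]].mean())
        between_vals.append(r[~same[iu]].mean())
    assert np.mean(within_vals) == pytest.approx(0.5, abs=0.05)
    assert np.mean(between_vals) == pytest.approx(0.1, abs=0.05)


def test_structural_matrices_symmetric_integer_zero_diagonal(tiny_spec):
    for rec in generate_structural_cohort(tiny_spec):
        fn = rec.fiber_counts
        assert np.array_equal(fn, fn.T)
        assert fn.dtype.kind == "i" and np.all(fn >= 0)
        assert np.all(np.diag(fn) == 0)


def test_structural_zero_between_rate_gives_zero_between_entries():
    spec = CohortSpec(
        group_sizes=(2, 2, 2),
        fn_mean_between=0.0,
        shortcut_density={"AVH": 0.0, "nAVH": 0.0, "HC": 0.0},
        seed=5,
    )
    modules = spec.module_labels
    between = modules[:, None] != modules[None, :]
    for rec in generate_structural_cohort(spec):
        assert np.all(rec.fiber_counts[between] == 0)


def test_structural_within_mean_recovered():
    spec = CohortSpec(seed=11)  # default 126 subjects
    records = generate_structural_cohort(spec)
    modules = spec.module_labels
    same = modules[:, None] == modules[None, :]
    iu = np.triu_indices(spec.n_rois, k=1)
    vals = [rec.fiber_counts[iu][same[iu]].mean() for rec in records]
    assert np.mean(vals) == pytest.approx(spec.fn_mean_within, rel=0.10)


def test_motion_trace_spikes():
    quiet = generate_motion_trace(180, spike_rate=0.0, seed=1)
    assert np.all(framewise_displacement(quiet).fd < 0.5)
    # binomial check pooled over seeds: ~18 spiked volumes per 180-volume run
    total, n_trials = 0, 0
    for seed in range(20):
        trace = generate_motion_trace(180, spike_rate=0.1, seed=seed)
        total += int((framewise_displacement(trace).fd > 0.5).sum())
        n_trials += 179
    from scipy.stats import binom

    lo, hi = binom.ppf([0.005, 0.995], n_trials, 0.1)
    assert lo <= total <= hi
    # determinism
    again = generate_motion_trace(180, spike_rate=0.1, seed=3)
    assert np.array_equal(
        again.translations, generate_motion_trace(180, 0.1, seed=3).translations
    )
    with pytest.raises(ValueError):
        generate_motion_trace(1, 0.0, seed=0)


def test_symptom_scores_distribution():
    scores = generate_symptom_scores(1000, seed=4)
    assert np.all(scores >= 0)
    assert scores.mean() == pytest.approx(AHRS_MEAN, abs=1.0)
    one = generate_symptom_scores(1, seed=8)
    assert one.shape == (1,) and one[0] >= 0
    assert np.array_equal(one, generate_symptom_scores(1, seed=8))
    assert not np.array_equal(
        generate_symptom_scores(5, seed=1), generate_symptom_scores(5, seed=2)
    )
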