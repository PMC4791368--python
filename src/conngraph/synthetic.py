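"""Synthetic three-group cohort generator with planted, controllable effects.

Emulates the data structure of a combined resting-state fMRI / diffusion
connectome study of auditory verbal hallucinations (AVH): an AVH patient
group, a non-hallucinating patient group (nAVH) and healthy controls (HC),
sizes 35/41/50, 90 AAL-style regions, 180 volumes at TR = 2 s for the
functional arm, and integer fiber-count matrices for the structural arm.

Group effects enter only through named parameters: the within-module signal
correlation ``rho_within`` per group (functional arm — reducing it lowers
clustering and efficiency and lengthens paths) and the long-range structural
shortcut density ``shortcut_density`` per group (structural arm — reducing
it lengthens paths).  Everything is deterministic given the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .preprocess import MotionTrace, SubjectTimeSeries

__all__ = [
    "GROUPS",
    "AHRS_MEAN",
    "AHRS_SD",
    "CohortSpec",
    "SubjectRecord",
    "modular_correlation",
    "generate_functional_cohort",
    "generate_structural_cohort",
    "generate_cohort",
    "generate_motion_trace",
    "generate_symptom_scores",
]

GROUPS = ("AVH", "nAVH", "HC")

# Symptom-severity scale parameters (AHRS total, patient population mean +- SD)
AHRS_MEAN = 23.9
AHRS_SD = 8.4

# Internal stream labels so functional / structural / symptom generation draw
# from independent, reproducible substreams of the same master seed.
_STREAM_FUNCTIONAL = 1
_STREAM_STRUCTURAL = 2
_STREAM_SYMPTOMS = 3


@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters for one synthetic cohort.

    Defaults are the study conditions: group sizes 35/41/50 (AVH/nAVH/HC),
    90 ROIs in 6 modules, 180 volumes at TR = 2 s.  ``rho_within`` and
    ``shortcut_density`` are per-group; the patient values are calibrated so
    the planted group effect on the downstream network metrics is a
    standardized difference of roughly one within-group SD.
    """

    n_rois: int = 90
    n_volumes: int = 180
    tr: float = 2.0
    group_sizes: tuple[int, int, int] = (35, 41, 50)  # AVH, nAVH, HC
    n_modules: int = 6
    rho_within: Mapping[str, float] = field(
        default_factory=lambda: {"AVH": 0.34, "nAVH": 0.34, "HC": 0.44}
    )
    rho_between: float = 0.08
    rho_homotopic: float = 0.60
    fn_mean_within: float = 30.0
    fn_mean_between: float = 1.0
    fn_dispersion: float = 8.0
    shortcut_density: Mapping[str, float] = field(
        default_factory=lambda: {"AVH": 0.030, "nAVH": 0.060, "HC": 0.060}
    )
    spike_rate: float = 0.02
    nuisance_coupling: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois % self.n_modules != 0:
            raise ValueError("n_rois must be divisible by n_modules")
        if any(n < 2 for n in self.group_sizes) or len(self.group_sizes) != 3:
            raise ValueError("group_sizes must be three counts, all >= 2")
        for g in GROUPS:
            rw = self.rho_within[g]
            # rho_between == rho_within is only meaningful in the fully
            # uncorrelated degenerate case (both 0)
            ok = (0 <= self.rho_between < rw < 1) or (
                self.rho_between == rw == 0
            )
            if not ok:
                raise ValueError(
                    f"need 0 <= rho_between < rho_within < 1; group {g} has "
                    f"(rho_within={rw}, rho_between={self.rho_between})"
                )
            if not 0 <= self.shortcut_density[g] < 1:
                raise ValueError(f"shortcut_density[{g}] must be in [0, 1)")
        if self.rho_homotopic and not 0 <= self.rho_homotopic < 1:
            raise ValueError("rho_homotopic must be in [0, 1)")
        if self.fn_mean_within < 0 or self.fn_mean_between < 0:
            raise ValueError("fiber-count means must be non-negative")
        if self.fn_dispersion <= 0:
            raise ValueError("fn_dispersion must be positive")
        if not 0 <= self.spike_rate < 1:
            raise ValueError("spike_rate must be in [0, 1)")
        if self.n_volumes < 2:
            raise ValueError("n_volumes must be at least 2")

    @property
    def module_labels(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_modules), self.n_rois // self.n_modules)


@dataclass
class SubjectRecord:
    """One subject's simulated data; modality fields are filled per arm."""

    subject_id: str
    group_label: str
    timeseries: SubjectTimeSeries | None = None
    motion: MotionTrace | None = None
    nuisance_signals: np.ndarray | None = None  # (n_volumes, 3): global, wm, csf
    fiber_counts: np.ndarray | None = None
    ahrs_total: float | None = None

    def __post_init__(self) -> None:
        if self.group_label not in GROUPS:
            raise ValueError(f"unknown group label {self.group_label!r}")
        if (self.ahrs_total is not None) != (self.group_label == "AVH"):
            raise ValueError("ahrs_total must be present iff group_label == 'AVH'")


def modular_correlation(
    n_rois: int,
    n_modules: int,
    rho_within: float,
    rho_between: float,
    rho_homotopic: float = 0.0,
) -> np.ndarray:
    """Block correlation matrix: rho_within inside modules, rho_between
    across, plus an optional third level of strong homotopic pairs.

    When ``rho_homotopic`` > 0 and ``n_rois`` is even, ROI i is paired with
    ROI i + n_rois/2 (left/right hemisphere ordering) at that correlation,
    emulating the strong inter-hemispheric homologue connectivity of real
    resting-state data.  These pairs are the strongest correlations in the
    matrix and therefore pin the weight scale that the max-normalized graph
    metrics divide by, independently of the group's rho_within.

    Raises if the requested structure is not positive definite (so it cannot
    be a valid MVN correlation matrix).
    """
    if n_rois % n_modules != 0:
        raise ValueError("n_rois must be divisible by n_modules")
    labels = np.repeat(np.arange(n_modules), n_rois // n_modules)
    corr = np.where(labels[:, None] == labels[None, :], rho_within, rho_between)
    if rho_homotopic > 0 and n_rois % 2 == 0:
        half = n_rois // 2
        idx = np.arange(half)
        corr[idx, idx + half] = rho_homotopic
        corr[idx + half, idx] = rho_homotopic
    np.fill_diagonal(corr, 1.0)
    try:
        np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        raise ValueError(
            "requested correlation structure is not positive definite: "
            f"(rho_within={rho_within}, rho_between={rho_between}, "
            f"rho_homotopic={rho_homotopic})"
        ) from None
    return corr


def _smooth_series(n: int, rng: np.random.Generator, ar: float = 0.9) -> np.ndarray:
    """Standardized AR(1) series used as a fabricated nuisance signal."""
    eps = rng.standard_normal(n) * np.sqrt(1.0 - ar**2)
    x = np.empty(n)
    x[0] = rng.standard_normal()
    for t in range(1, n):
        x[t] = ar * x[t - 1] + eps[t]
    return x


def _motion_with_spikes(
    n_volumes: int, spike_rate: float, rng: np.random.Generator
) -> tuple[MotionTrace, np.ndarray]:
    """Smooth low-amplitude drift plus step displacements at spike volumes.

    Drift increments are clipped so spike-free FD stays below 0.5 mm; each
    spike is a persistent 1.5 mm translation step, so FD exceeds 0.5 mm at
    exactly the spiked volume.
    """
    if n_volumes < 2:
        raise ValueError("a motion trace needs at least 2 volumes")
    dtrans = np.clip(rng.normal(0.0, 0.02, (n_volumes, 3)), -0.07, 0.07)
    drot = np.clip(rng.normal(0.0, 2e-4, (n_volumes, 3)), -7e-4, 7e-4)
    dtrans[0] = drot[0] = 0.0
    spikes = np.flatnonzero(rng.random(n_volumes - 1) < spike_rate) + 1
    signs = rng.choice([-1.0, 1.0], size=spikes.size)
    dtrans[spikes, 0] += 1.5 * signs
    return (
        MotionTrace(np.cumsum(dtrans, axis=0), np.cumsum(drot, axis=0)),
        spikes,
    )


def generate_motion_trace(
    n_volumes: int, spike_rate: float, seed: int
) -> MotionTrace:
    """Six-parameter rigid-body trace with an expected ``spike_rate`` fraction
    of volumes whose framewise displacement exceeds 0.5 mm."""
    if not 0 <= spike_rate < 1:
        raise ValueError("spike_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    trace, _ = _motion_with_spikes(n_volumes, spike_rate, rng)
    return trace


def generate_symptom_scores(n: int, seed: int) -> np.ndarray:
    """AHRS total scores: normal(23.9, 8.4) truncated at zero."""
    if n < 1:
        raise ValueError("n must be at least 1")
    a = (0.0 - AHRS_MEAN) / AHRS_SD
    dist = stats.truncnorm(a, np.inf, loc=AHRS_MEAN, scale=AHRS_SD)
    return np.asarray(dist.rvs(size=n, random_state=np.random.default_rng(seed)))


def _group_plan(spec: CohortSpec) -> list[tuple[str, str]]:
    """Stable (subject_id, group) enumeration: AVH first, then nAVH, then HC."""
    plan = []
    for group, size in zip(GROUPS, spec.group_sizes):
        for i in range(size):
            plan.append((f"{group}{i + 1:03d}", group))
    return plan


def _symptom_lookup(spec: CohortSpec) -> dict[str, float]:
    n_avh = spec.group_sizes[0]
    seed = int(np.random.SeedSequence([spec.seed, _STREAM_SYMPTOMS]).generate_state(1)[0] % (2**31))
    scores = generate_symptom_scores(n_avh, seed)
    return {f"AVH{i + 1:03d}": float(s) for i, s in enumerate(scores)}


def generate_functional_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Simulate the functional arm: per subject an ROI x volume matrix drawn
    from a zero-mean MVN with the group's modular correlation structure,
    contaminated by fabricated global/WM/CSF signals and motion-spike
    artifacts, plus the matching motion trace."""
    root = np.random.SeedSequence([spec.seed, _STREAM_FUNCTIONAL])
    children = root.spawn(sum(spec.group_sizes))
    ahrs = _symptom_lookup(spec)
    chol = {
        g: np.linalg.cholesky(
            modular_correlation(
                spec.n_rois,
                spec.n_modules,
                spec.rho_within[g],
                spec.rho_between,
                spec.rho_homotopic,
            )
        )
        for g in GROUPS
    }
    records = []
    for (subject_id, group), child in zip(_group_plan(spec), children):
        rng = np.random.default_rng(child)
        latent = rng.standard_normal((spec.n_volumes, spec.n_rois)) @ chol[group].T
        nuis = np.column_stack(
            [_smooth_series(spec.n_volumes, rng) for _ in range(3)]
        )
        motion, spikes = _motion_with_spikes(spec.n_volumes, spec.spike_rate, rng)
        mix = spec.nuisance_coupling * np.array([1.0, 0.6, 0.4])
        signal = latent + (nuis @ mix)[:, None]  # shared contaminant in every ROI
        # spike artifact: shared amplitude jump at high-motion volumes
        signal[spikes, :] += 4.0
        records.append(
            SubjectRecord(
                subject_id=subject_id,
                group_label=group,
                timeseries=SubjectTimeSeries(signal.T, spec.tr),
                motion=motion,
                nuisance_signals=nuis,
                ahrs_total=ahrs.get(subject_id),
            )
        )
    return records


def generate_structural_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Simulate the structural arm: symmetric non-negative integer
    fiber-count matrices with negative-binomial counts (mean
    ``fn_mean_within`` inside modules, ``fn_mean_between`` across), plus
    long-range shortcut edges at the group's ``shortcut_density``."""
    root = np.random.SeedSequence([spec.seed, _STREAM_STRUCTURAL])
    children = root.spawn(sum(spec.group_sizes))
    ahrs = _symptom_lookup(spec)
    labels = spec.module_labels
    same_module = labels[:, None] == labels[None, :]
    iu = np.triu_indices(spec.n_rois, k=1)
    within_pair = same_module[iu]
    records = []
    for (subject_id, group), child in zip(_group_plan(spec), children):
        rng = np.random.default_rng(child)
        means = np.where(within_pair, spec.fn_mean_within, spec.fn_mean_between)
        shortcut = (~within_pair) & (
            rng.random(within_pair.size) < spec.shortcut_density[group]
        )
        means = np.where(shortcut, spec.fn_mean_within, means)
        counts = _negative_binomial(means, spec.fn_dispersion, rng)
        fn = np.zeros((spec.n_rois, spec.n_rois), dtype=int)
        fn[iu] = counts
        fn = fn + fn.T
        records.append(
            SubjectRecord(
                subject_id=subject_id,
                group_label=group,
                fiber_counts=fn,
                ahrs_total=ahrs.get(subject_id),
            )
        )
    return records


def _negative_binomial(
    means: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    """NB(mean m, size k): variance m + m^2/k; m = 0 yields exact zeros."""
    out = np.zeros(means.shape, dtype=int)
    pos = means > 0
    if np.any(pos):
        p = dispersion / (dispersion + means[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Both arms merged per subject (same ids, groups and symptom scores)."""
    functional = generate_functional_cohort(spec)
    structural = {r.subject_id: r for r in generate_structural_cohort(spec)}
    for rec in functional:
        rec.fiber_counts = structural[rec.subject_id].fiber_counts
    return functional
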