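"""Conditioning of ROI time series prior to network construction.

The pipeline starts from region-averaged resting-state signals and the
six rigid-body motion parameters estimated during realignment.  It applies,
in fixed order: discarding of initial non-equilibrium volumes, framewise-
displacement (FD) computation, spike-volume detection, joint nuisance
regression (motion, motion derivatives, global/white-matter/CSF signals and
one indicator per spike volume), and band-pass filtering.

Voxel-level operations (slice timing, realignment estimation, segmentation,
spatial normalization) are out of scope: global, white-matter and CSF
signals are accepted as input columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "SubjectTimeSeries",
    "MotionTrace",
    "FDSeries",
    "NuisanceMatrix",
    "discard_initial_volumes",
    "framewise_displacement",
    "detect_spike_volumes",
    "build_nuisance_matrix",
    "regress_nuisance",
    "bandpass_filter",
    "preprocess_subject",
]


@dataclass(frozen=True)
class SubjectTimeSeries:
    """ROI-by-volume signal matrix with its sampling interval (TR, seconds)."""

    values: np.ndarray  # shape (n_rois, n_volumes)
    tr: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("time series must be a 2-D (ROI x volume) matrix")
        if values.shape[1] < 2:
            raise ValueError("time series must contain at least 2 volumes")
        if not np.all(np.isfinite(values)):
            raise ValueError("time series contains non-finite values")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        object.__setattr__(self, "values", values)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class MotionTrace:
    """Per-volume rigid-body parameters: translations (mm), rotations (rad)."""

    translations: np.ndarray  # shape (n_volumes, 3)
    rotations: np.ndarray  # shape (n_volumes, 3)

    def __post_init__(self) -> None:
        t = np.asarray(self.translations, dtype=float)
        r = np.asarray(self.rotations, dtype=float)
        if t.shape != r.shape or t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("translations and rotations must both be (n_volumes, 3)")
        object.__setattr__(self, "translations", t)
        object.__setattr__(self, "rotations", r)

    @property
    def n_volumes(self) -> int:
        return self.translations.shape[0]

    def slice(self, start: int) -> "MotionTrace":
        """Drop the first ``start`` volumes (alignment with discarded scans)."""
        return MotionTrace(self.translations[start:], self.rotations[start:])


@dataclass(frozen=True)
class FDSeries:
    """Power-style framewise displacement per volume, mm; fd[0] is defined as 0."""

    fd: np.ndarray

    def __post_init__(self) -> None:
        fd = np.asarray(self.fd, dtype=float)
        if fd.ndim != 1 or np.any(fd < 0) or not np.all(np.isfinite(fd)):
            raise ValueError("fd must be a 1-D non-negative finite series")
        object.__setattr__(self, "fd", fd)

    @property
    def mean_fd(self) -> float:
        """Mean over volumes 2..T (fd[0] carries no motion information)."""
        return float(self.fd[1:].mean()) if self.fd.size > 1 else 0.0


@dataclass(frozen=True)
class NuisanceMatrix:
    """Per-volume nuisance regressors with column labels.

    Columns: 6 motion parameters, their 6 backward first differences
    (leading 0), global signal, white-matter signal, CSF signal, and one
    one-hot indicator column per spike volume — 15 + n_spikes in total.
    """

    columns: np.ndarray  # shape (n_volumes, n_regressors)
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        cols = np.asarray(self.columns, dtype=float)
        if cols.ndim != 2 or cols.shape[1] != len(self.labels):
            raise ValueError("column count must match label count")
        object.__setattr__(self, "columns", cols)
        object.__setattr__(self, "labels", tuple(self.labels))


def discard_initial_volumes(ts: SubjectTimeSeries, k: int = 10) -> SubjectTimeSeries:
    """Drop the first ``k`` volumes (signal-equilibration scans)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= ts.n_volumes:
        raise ValueError(
            f"cannot discard {k} volumes from a series of {ts.n_volumes}"
        )
    if k == 0:
        return ts
    return SubjectTimeSeries(ts.values[:, k:], ts.tr)


def framewise_displacement(
    motion: MotionTrace, rotation_radius_mm: float = 50.0
) -> FDSeries:
    """Scalar FD: sum of absolute volume-to-volume parameter changes.

    Rotations are converted to arc displacement on a sphere of
    ``rotation_radius_mm`` (default 50 mm).  fd[0] = 0.
    """
    if motion.n_volumes < 2:
        raise ValueError("FD requires at least 2 volumes")
    if not (
        np.all(np.isfinite(motion.translations))
        and np.all(np.isfinite(motion.rotations))
    ):
        raise ValueError("motion parameters contain non-finite values")
    dt = np.abs(np.diff(motion.translations, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(motion.rotations, axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], dt + rotation_radius_mm * dr])
    return FDSeries(fd)


def detect_spike_volumes(fd: FDSeries, threshold: float = 0.5) -> list[int]:
    """Indices of volumes whose FD strictly exceeds ``threshold`` (mm)."""
    return [int(i) for i in np.flatnonzero(fd.fd > threshold)]


def build_nuisance_matrix(
    motion: MotionTrace,
    global_sig: np.ndarray,
    wm_sig: np.ndarray,
    csf_sig: np.ndarray,
    spikes: list[int] | None = None,
) -> NuisanceMatrix:
    """Assemble the joint nuisance design (15 continuous + spike columns)."""
    spikes = sorted(spikes or [])
    t = motion.n_volumes
    sigs = [np.asarray(s, dtype=float).ravel() for s in (global_sig, wm_sig, csf_sig)]
    for name, s in zip(("global", "wm", "csf"), sigs):
        if s.size != t:
            raise ValueError(
                f"{name} signal has {s.size} volumes, motion has {t}"
            )
    params = np.hstack([motion.translations, motion.rotations])
    derivs = np.vstack([np.zeros((1, 6)), np.diff(params, axis=0)])
    cols = [params, derivs, np.column_stack(sigs)]
    labels = (
        ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
        + ["d_trans_x", "d_trans_y", "d_trans_z", "d_rot_x", "d_rot_y", "d_rot_z"]
        + ["global", "wm", "csf"]
    )
    for s in spikes:
        if not 0 <= s < t:
            raise ValueError(f"spike index {s} out of range for {t} volumes")
        onehot = np.zeros((t, 1))
        onehot[s, 0] = 1.0
        cols.append(onehot)
        labels.append(f"spike_{s}")
    return NuisanceMatrix(np.hstack(cols), tuple(labels))


def regress_nuisance(
    ts: SubjectTimeSeries, nuisance: NuisanceMatrix
) -> SubjectTimeSeries:
    """Replace each ROI series by its residual against the nuisance design.

    An intercept is always included.  Collinear columns are pruned (with a
    warning naming them) via pivoted QR before projecting, so the retained
    design has full column rank; residuals are computed by orthogonal
    projection and are therefore orthogonal to every retained column to
    machine precision.
    """
    if nuisance.columns.shape[0] != ts.n_volumes:
        raise ValueError(
            f"nuisance design has {nuisance.columns.shape[0]} volumes, "
            f"time series has {ts.n_volumes}"
        )
    x = np.column_stack([np.ones(ts.n_volumes), nuisance.columns])
    labels = ("intercept",) + nuisance.labels
    _, r, piv = linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    keep = np.sort(piv[:rank])
    if rank < x.shape[1]:
        dropped = [labels[i] for i in np.sort(piv[rank:])]
        warnings.warn(
            f"dropping collinear nuisance columns: {', '.join(dropped)}",
            stacklevel=2,
        )
    q, _ = linalg.qr(x[:, keep], mode="economic")
    resid = ts.values - (ts.values @ q) @ q.T
    return SubjectTimeSeries(resid, ts.tr)


def bandpass_filter(
    ts: SubjectTimeSeries, low: float = 0.01, high: float = 0.08
) -> SubjectTimeSeries:
    """Ideal rectangular band-pass on the discrete spectrum.

    Frequency bins f with low <= f <= high are retained; everything else,
    including the 0 Hz mean, is removed exactly.
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    if not (0 <= low < high):
        raise ValueError(f"need 0 <= low < high, got ({low}, {high})")
    if high >= nyquist:
        raise ValueError(
            f"high edge {high} Hz is not below the Nyquist frequency {nyquist} Hz"
        )
    t = ts.n_volumes
    freqs = np.fft.rfftfreq(t, d=ts.tr)
    keep = (freqs >= low) & (freqs <= high)
    keep[0] = False  # mean always removed
    spectrum = np.fft.rfft(ts.values, axis=1)
    spectrum[:, ~keep] = 0.0
    return SubjectTimeSeries(np.fft.irfft(spectrum, n=t, axis=1), ts.tr)


def preprocess_subject(
    ts: SubjectTimeSeries,
    motion: MotionTrace,
    global_sig: np.ndarray,
    wm_sig: np.ndarray,
    csf_sig: np.ndarray,
    k_discard: int = 10,
    fd_threshold: float = 0.5,
    band: tuple[float, float] = (0.01, 0.08),
) -> tuple[SubjectTimeSeries, FDSeries, list[int]]:
    """Full conditioning chain for one subject.

    Order is fixed: discard -> FD/spike detection -> joint nuisance
    regression (spike indicators included) -> band-pass.  Motion and
    signal columns are truncated in lockstep with the discarded volumes.
    Returns the filtered series, the FD series and the spike indices
    (both on the post-discard volume grid).
    """
    clean = discard_initial_volumes(ts, k_discard)
    motion_c = motion.slice(k_discard)
    g, w, c = (np.asarray(s, dtype=float).ravel()[k_discard:] for s in (global_sig, wm_sig, csf_sig))
    fd = framewise_displacement(motion_c)
    spikes = detect_spike_volumes(fd, fd_threshold)
    design = build_nuisance_matrix(motion_c, g, w, c, spikes)
    resid = regress_nuisance(clean, design)
    filtered = bandpass_filter(resid, *band)
    return filtered, fd, spikes
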