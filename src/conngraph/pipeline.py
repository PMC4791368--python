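"""End-to-end orchestration of the functional and structural arms.

Functional arm: discard -> FD/spike detection -> joint nuisance regression
-> band-pass -> correlation -> significance thresholding (each configured
scheme) -> global metrics -> null-normalized metrics -> permutation group
statistics and symptom correlations.

Structural arm: fiber-count threshold -> global metrics -> null-normalized
metrics -> the same statistics.

Everything is reproducible from the master seed: per-subject and per-stage
sub-seeds are spawned deterministically.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .config import RunConfig, stage_seed
from .metrics import basic_properties, global_metrics
from .networks import correlation_matrix, threshold_functional, threshold_structural
from .nulls import NullEnsembleSpec, normalized_metrics
from .preprocess import preprocess_subject
from .stats import permutation_anova, permutation_pairwise, spearman_correlation
from .synthetic import GROUPS, SubjectRecord

__all__ = [
    "RAW_METRICS",
    "NORMALIZED_METRICS",
    "build_functional_table",
    "build_structural_table",
    "compare_groups",
    "correlate_symptoms",
    "run_functional_arm",
    "run_structural_arm",
]

log = logging.getLogger("conngraph")

RAW_METRICS = ("cp", "lp", "eg", "eloc")
NORMALIZED_METRICS = ("gamma", "lam", "sigma", "neg", "neloc")
BASIC_METRICS = ("density", "strength", "largest_component")
PAIRS = (("AVH", "HC"), ("nAVH", "HC"), ("AVH", "nAVH"))

# maximum head motion accepted at screening: 2 mm translation or 2 degrees
_SCREEN_TRANS_MM = 2.0
_SCREEN_ROT_RAD = np.deg2rad(2.0)


def _metric_row(graph, null_spec: NullEnsembleSpec | None) -> dict[str, float]:
    gm = global_metrics(graph)
    row = gm.as_dict()
    row.update(basic_properties(graph).as_dict())
    if null_spec is not None:
        row.update(normalized_metrics(graph, null_spec, observed=gm).as_dict())
    return row


def build_functional_table(
    records: list[SubjectRecord], cfg: RunConfig
) -> pd.DataFrame:
    """Per-subject metric rows for every configured threshold scheme."""
    rows, errors = [], []
    for idx, rec in enumerate(records):
        try:
            clean, fd, spikes = preprocess_subject(
                rec.timeseries,
                rec.motion,
                rec.nuisance_signals[:, 0],
                rec.nuisance_signals[:, 1],
                rec.nuisance_signals[:, 2],
                k_discard=cfg.k_discard,
                fd_threshold=cfg.fd_threshold,
                band=cfg.band,
            )
            corr = correlation_matrix(clean)
            motion_ok = bool(
                np.abs(rec.motion.translations).max() < _SCREEN_TRANS_MM
                and np.abs(rec.motion.rotations).max() < _SCREEN_ROT_RAD
            )
            for scheme in cfg.schemes:
                graph = threshold_functional(corr, scheme)
                null_spec = (
                    NullEnsembleSpec(
                        cfg.n_null,
                        cfg.swaps_per_edge,
                        stage_seed(cfg.seed, "nulls", idx),
                    )
                    if cfg.n_null > 0
                    else None
                )
                row = {
                    "subject_id": rec.subject_id,
                    "group": rec.group_label,
                    "modality": "functional",
                    "scheme": scheme.name,
                    "mean_fd": fd.mean_fd,
                    "n_spikes": len(spikes),
                    "motion_ok": motion_ok,
                }
                row.update(_metric_row(graph, null_spec))
                rows.append(row)
        except Exception as exc:  # collected, reported together
            errors.append(f"{rec.subject_id}: {exc}")
            log.warning("subject %s failed: %s", rec.subject_id, exc)
    unique = {(r["subject_id"], r["group"]) for r in rows}
    _check_enough_subjects(
        [{"group": g, "subject_id": s} for s, g in unique],
        errors,
        _input_counts(records),
    )
    return pd.DataFrame(rows)


def build_structural_table(
    records: list[SubjectRecord], cfg: RunConfig
) -> pd.DataFrame:
    rows, errors = [], []
    for idx, rec in enumerate(records):
        try:
            graph = threshold_structural(rec.fiber_counts, cfg.min_fibers)
            null_spec = (
                NullEnsembleSpec(
                    cfg.n_null,
                    cfg.swaps_per_edge,
                    stage_seed(cfg.seed, "nulls", idx),
                )
                if cfg.n_null > 0
                else None
            )
            row = {
                "subject_id": rec.subject_id,
                "group": rec.group_label,
                "modality": "structural",
                "scheme": f"fn{cfg.min_fibers}",
            }
            row.update(_metric_row(graph, null_spec))
            rows.append(row)
        except Exception as exc:
            errors.append(f"{rec.subject_id}: {exc}")
            log.warning("subject %s failed: %s", rec.subject_id, exc)
    _check_enough_subjects(rows, errors, _input_counts(records))
    return pd.DataFrame(rows)


def _check_enough_subjects(
    rows: list[dict], errors: list[str], input_counts: dict[str, int]
) -> None:
    """Abort if per-subject failures push a usable group below 2 subjects."""
    counts = {g: 0 for g in GROUPS}
    for row in rows:
        counts[row["group"]] = counts[row["group"]] + 1
    dropped = [
        g for g, n_in in input_counts.items() if n_in >= 2 and counts[g] < 2
    ]
    if errors and dropped:
        raise RuntimeError(
            f"group(s) {dropped} dropped below 2 subjects; "
            f"subject errors: {errors}"
        )
    if errors:
        warnings.warn(f"{len(errors)} subject(s) failed: {errors}", stacklevel=3)


def _input_counts(records: list[SubjectRecord]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in records:
        counts[rec.group_label] = counts.get(rec.group_label, 0) + 1
    return counts


def compare_groups(
    table: pd.DataFrame,
    cfg: RunConfig,
    metrics: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Permutation ANOVA + pairwise post-hocs per metric, scheme and modality."""
    results = []
    for (modality, scheme), sub in table.groupby(["modality", "scheme"], sort=False):
        labels = sub["group"].to_numpy()
        cols = metrics or tuple(
            m
            for m in RAW_METRICS + NORMALIZED_METRICS + BASIC_METRICS
            if m in sub.columns
        )
        for j, metric in enumerate(cols):
            values = sub[metric].to_numpy(dtype=float)
            res = permutation_anova(
                values,
                labels,
                n_perm=cfg.n_perm,
                seed=stage_seed(cfg.seed, "anova", j),
                metric=metric,
            )
            row = {
                "modality": modality,
                "scheme": scheme,
                "metric": metric,
                "f_obs": res.f_obs,
                "p_perm": res.p_perm,
                "n_perm": cfg.n_perm,
            }
            for pi, (g1, g2) in enumerate(PAIRS):
                mask = np.isin(labels, [g1, g2])
                if mask.sum() and len(set(labels[mask])) == 2:
                    row[f"p_{g1}_vs_{g2}"] = permutation_pairwise(
                        values[mask],
                        labels[mask],
                        n_perm=cfg.n_perm,
                        seed=stage_seed(cfg.seed, "pairwise", j * 10 + pi),
                    )
                # direction of the difference in group means
                if mask.sum():
                    m1 = values[labels == g1].mean() if (labels == g1).any() else np.nan
                    m2 = values[labels == g2].mean() if (labels == g2).any() else np.nan
                    row[f"d_{g1}_vs_{g2}"] = m1 - m2
            results.append(row)
    return pd.DataFrame(results)


def correlate_symptoms(
    table: pd.DataFrame,
    ahrs: dict[str, float],
    metrics: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Spearman correlation of each metric with AHRS total in the AVH group."""
    results = []
    avh = table[table["group"] == "AVH"]
    for (modality, scheme), sub in avh.groupby(["modality", "scheme"], sort=False):
        if len(sub) < 3:
            log.warning(
                "skipping symptom correlations for %s/%s: only %d AVH subjects",
                modality,
                scheme,
                len(sub),
            )
            continue
        scores = np.array([ahrs[s] for s in sub["subject_id"]])
        cols = metrics or tuple(
            m
            for m in RAW_METRICS + NORMALIZED_METRICS
            if m in sub.columns
        )
        for metric in cols:
            res = spearman_correlation(
                sub[metric].to_numpy(dtype=float), scores, metric=metric
            )
            results.append(
                {
                    "modality": modality,
                    "scheme": scheme,
                    "metric": metric,
                    "rho": res.rho,
                    "p": res.p,
                    "n": res.n,
                }
            )
    return pd.DataFrame(results)


def _persist(
    cfg: RunConfig,
    arm: str,
    table: pd.DataFrame,
    comparisons: pd.DataFrame,
    correlations: pd.DataFrame,
) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / f"{arm}_metrics.tsv", sep="\t", index=False, float_format="%.12g")
    comparisons.to_csv(
        out / f"{arm}_group_tests.tsv", sep="\t", index=False, float_format="%.12g"
    )
    correlations.to_csv(
        out / f"{arm}_symptom_correlations.tsv", sep="\t", index=False, float_format="%.12g"
    )
    from . import __version__

    record = {"arm": arm, "config": cfg.to_dict(), "version": __version__}
    with open(out / f"{arm}_run_record.json", "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)


def _ahrs_lookup(records: list[SubjectRecord]) -> dict[str, float]:
    return {
        r.subject_id: r.ahrs_total for r in records if r.ahrs_total is not None
    }


def run_functional_arm(
    cfg: RunConfig, records: list[SubjectRecord] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full functional pipeline; returns (metric table, group tests, correlations)."""
    if records is None:
        if cfg.manifest is None:
            raise ValueError("config needs a manifest path or in-memory records")
        records, _ = cio.read_cohort(cfg.manifest)
    records = [r for r in records if r.timeseries is not None]
    log.info("functional arm: %d subjects", len(records))
    table = build_functional_table(records, cfg)
    comparisons = compare_groups(table, cfg)
    correlations = correlate_symptoms(table, _ahrs_lookup(records))
    _persist(cfg, "functional", table, comparisons, correlations)
    return table, comparisons, correlations


def run_structural_arm(
    cfg: RunConfig, records: list[SubjectRecord] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full structural pipeline; returns (metric table, group tests, correlations)."""
    if records is None:
        if cfg.manifest is None:
            raise ValueError("config needs a manifest path or in-memory records")
        records, _ = cio.read_cohort(cfg.manifest)
    records = [r for r in records if r.fiber_counts is not None]
    log.info("structural arm: %d subjects", len(records))
    table = build_structural_table(records, cfg)
    comparisons = compare_groups(table, cfg)
    correlations = correlate_symptoms(table, _ahrs_lookup(records))
    _persist(cfg, "structural", table, comparisons, correlations)
    return table, comparisons, correlations
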