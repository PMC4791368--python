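"""File I/O round trips, pipeline orchestration and CLI plumbing."""

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from conngraph import (
    CohortSpec,
    MotionTrace,
    RunConfig,
    SubjectRecord,
    SubjectTimeSeries,
    ThresholdScheme,
    generate_cohort,
)
from conngraph import io as cio
from conngraph.cli import main
from conngraph.pipeline import (
    build_functional_table,
    build_structural_table,
    compare_groups,
    run_functional_arm,
    run_structural_arm,
)


def test_matrix_round_trip(tmp_path, rng):
    m = rng.normal(size=(90, 90))
    m = (m + m.T) / 2
    labels = cio.roi_labels(90)
    path = tmp_path / "m.tsv"
    cio.write_matrix(m, path, labels)
    back, back_labels = cio.read_matrix(path)
    assert back_labels == labels
    assert np.allclose(back, m, rtol=1e-12, atol=1e-14)


def test_ragged_row_rejected_with_coordinates(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("a\tb\n1\t2\n3\n")
    with pytest.raises(ValueError, match="row 3"):
        cio.read_matrix(path)


def test_non_numeric_cell_rejected(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("roi\ta\tb\na\t1\tx\nb\t2\t3\n")
    with pytest.raises(ValueError, match="non-numeric"):
        cio.read_matrix(path)


def test_matrix_reordered_to_manifest_order(tmp_path):
    labels = ["r1", "r2", "r3"]
    m = np.arange(9.0).reshape(3, 3)
    m = (m + m.T) / 2
    path = tmp_path / "m.tsv"
    cio.write_matrix(m, path, ["r2", "r1", "r3"])
    with pytest.warns(UserWarning, match="reordering"):
        back, back_labels = cio.read_matrix(path, labels=labels)
    assert back_labels == labels
    perm = [1, 0, 2]
    assert np.allclose(back, m[np.ix_(perm, perm)])


def test_cohort_write_read_round_trip(tmp_path, tiny_spec):
    records = generate_cohort(tiny_spec)
    manifest = cio.write_cohort(records, tiny_spec, tmp_path / "cohort")
    back, spec = cio.read_cohort(manifest)
    assert spec == tiny_spec
    assert [r.subject_id for r in back] == [r.subject_id for r in records]
    for ra, rb in zip(records, back):
        assert np.allclose(ra.timeseries.values, rb.timeseries.values, atol=1e-9)
        assert np.array_equal(ra.fiber_counts, rb.fiber_counts)
        assert (ra.ahrs_total is None) == (rb.ahrs_total is None)


def _handwritten_records():
    """Three 4-ROI subjects, one per group, with trivially correlated series."""
    rng = np.random.default_rng(0)
    records = []
    for i, group in enumerate(("AVH", "nAVH", "HC")):
        t = 40
        base = rng.normal(size=t)
        values = np.vstack(
            [base, base + 0.1 * rng.normal(size=t), rng.normal(size=t), rng.normal(size=t)]
        )
        records.append(
            SubjectRecord(
                subject_id=f"S{i}",
                group_label=group,
                timeseries=SubjectTimeSeries(values, tr=2.0),
                motion=MotionTrace(np.zeros((t, 3)), np.zeros((t, 3))),
                nuisance_signals=rng.normal(size=(t, 3)),
                ahrs_total=20.0 if group == "AVH" else None,
            )
        )
    return records


def test_tiny_handwritten_cohort_produces_full_metric_table():
    cfg = RunConfig(
        n_null=0,
        k_discard=2,
        schemes=(ThresholdScheme(0.5, "none"),),
        band=(0.01, 0.2),
    )
    table = build_functional_table(_handwritten_records(), cfg)
    assert len(table) == 3
    for col in ("cp", "lp", "eg", "eloc", "density", "strength", "largest_component"):
        assert col in table.columns and table[col].notna().all()


def test_identical_fiber_matrices_give_p_one(tiny_spec):
    records = generate_cohort(tiny_spec)
    fn = records[0].fiber_counts
    for r in records:
        r.fiber_counts = fn
    cfg = RunConfig(n_null=0, n_perm=200, seed=1)
    table = build_structural_table(records, cfg)
    comp = compare_groups(table, cfg, metrics=("cp", "lp", "eg", "eloc"))
    assert np.all(comp["p_perm"] == 1.0)


def test_arm_runs_are_deterministic(tmp_path, tiny_spec):
    records = generate_cohort(tiny_spec)
    cfg = RunConfig(
        out_dir=str(tmp_path / "run1"), n_null=3, n_perm=100, seed=5,
        schemes=(ThresholdScheme(0.05, "bonferroni"),),
    )
    t1, c1, s1 = run_functional_arm(cfg, records=records)
    t2, c2, s2 = run_functional_arm(cfg.replace(out_dir=str(tmp_path / "run2")), records=records)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(c1, c2)
    st1, sc1, _ = run_structural_arm(cfg, records=records)
    st2, sc2, _ = run_structural_arm(cfg, records=records)
    pd.testing.assert_frame_equal(st1, st2)
    pd.testing.assert_frame_equal(sc1, sc2)
    # byte-identical persisted tables
    a = (tmp_path / "run1" / "functional_metrics.tsv").read_bytes()
    b = (tmp_path / "run2" / "functional_metrics.tsv").read_bytes()
    assert a == b


def test_cli_simulate_and_run_all(tmp_path):
    runner = CliRunner()
    cohort_dir = tmp_path / "cohort"
    res = runner.invoke(
        main,
        ["simulate", "--out-dir", str(cohort_dir), "--seed", "3",
         "--n-volumes", "60", "--group-sizes", "2,2,2"],
    )
    assert res.exit_code == 0, res.output
    assert (cohort_dir / "manifest.tsv").exists()
    out_dir = tmp_path / "results"
    res = runner.invoke(
        main,
        ["run-all", "--manifest", str(cohort_dir / "manifest.tsv"),
         "--out-dir", str(out_dir), "--seed", "1", "--n-null", "2",
         "--n-perm", "50"],
    )
    assert res.exit_code == 0, res.output
    for name in (
        "functional_metrics.tsv",
        "functional_group_tests.tsv",
        "structural_metrics.tsv",
        "structural_run_record.json",
    ):
        assert (out_dir / name).exists()
    table = pd.read_csv(out_dir / "functional_metrics.tsv", sep="\t")
    assert set(table["scheme"]) == {"p0.05_bonferroni", "p0.001_none", "p0.01_bonferroni"}
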