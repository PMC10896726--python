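"""Batch-correction methods and the three evaluation metrics."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from senmetflux.batch_correction import (ReferenceScheme, apply_method,
                                         benchmark_methods,
                                         bhattacharyya_distance,
                                         bhattacharyya_from_moments,
                                         eb_location_scale_adjust,
                                         quantile_normalize,
                                         reference_scale_normalize,
                                         repeatability, rsd, rsd_group)
from senmetflux.differential import log_transform
from senmetflux.io_model import OmicsMatrix, SampleMeta
from .conftest import make_matrix, make_meta


# --- r.s.d.

def test_rsd_group_oracle():
    assert rsd_group([1.0, 2.0, 3.0]) == pytest.approx(0.5)


def test_rsd_group_degenerate():
    assert np.isnan(rsd_group([5.0]))
    assert np.isnan(rsd_group([1.0, -1.0]))  # zero mean


@given(st.lists(st.floats(0.5, 100.0), min_size=2, max_size=8),
       st.floats(0.1, 10.0))
@settings(max_examples=50, deadline=None)
def test_rsd_group_scale_invariant(values, c):
    r = rsd_group(values)
    if np.isfinite(r):
        assert rsd_group([c * v for v in values]) == pytest.approx(r, rel=1e-9)


def test_rsd_table_groups_by_identity():
    meta = make_meta(n_batches=3, timepoints=(0.0, 4.0), n_replicates=1)
    mat = make_matrix(meta, n_features=2, seed=1)
    table = rsd(mat, meta)
    # one row per (feature, identity); 2 identities x 2 features
    assert len(table) == 4
    ident = (0.0, 1, "baseline")
    cols = [s for s in mat.sample_ids if meta.identity(s) == ident]
    expected = rsd_group(mat.values.loc["met000", cols])
    got = table[(table["feature_id"] == "met000")
                & (table["timepoint_days"] == 0.0)]["rsd"].iloc[0]
    assert got == pytest.approx(expected)


# --- repeatability

def _repeat_mat(groups):
    """Matrix/meta where each inner list is one identity measured across batches."""
    rows, cols, vals = [], [], []
    for t, vs in enumerate(groups):
        for b, v in enumerate(vs):
            sid = f"B{b + 1}_t{t}"
            rows.append((sid, f"B{b + 1}", float(t), 1,
                         "baseline" if t == 0 else "treated"))
            cols.append(sid)
            vals.append(v)
    meta = SampleMeta(pd.DataFrame(rows, columns=["sample_id", "batch",
                                                  "timepoint_days",
                                                  "replicate", "role"]))
    mat = OmicsMatrix(pd.DataFrame([vals], index=["f1"], columns=cols),
                      modality="metabolite", scale="log")
    return mat, meta


def test_repeatability_oracles():
    mat, meta = _repeat_mat([[1.0, 1.0], [3.0, 3.0]])
    assert repeatability(mat, meta)["f1"] == pytest.approx(1.0)
    mat, meta = _repeat_mat([[0.0, 2.0], [1.0, 3.0]])
    assert repeatability(mat, meta)["f1"] == pytest.approx(0.2)


def test_repeatability_needs_two_identities():
    mat, meta = _repeat_mat([[1.0, 2.0]])
    with pytest.raises(ValueError, match=">= 2 sample identities"):
        repeatability(mat, meta)


# --- Bhattacharyya

def test_bhattacharyya_identical_clusters_zero():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(30, 2))
    assert bhattacharyya_distance(X, X.copy()) == pytest.approx(0.0, abs=1e-9)


def test_bhattacharyya_1d_closed_form():
    # equal unit variances, mean difference 2: DB = (1/8) * 4 = 0.5
    db = bhattacharyya_from_moments([0.0], [[1.0]], [2.0], [[1.0]], ridge=0.0)
    assert db == pytest.approx(0.5, abs=1e-9)


def test_bhattacharyya_as_printed_differs_when_scales_differ():
    std = bhattacharyya_from_moments([0.0], [[1.0]], [0.0], [[4.0]], ridge=0.0)
    printed = bhattacharyya_from_moments([0.0], [[1.0]], [0.0], [[4.0]],
                                         as_printed=True, ridge=0.0)
    # printed variant drops the square root over det S1 det S2, i.e. it
    # subtracts the full log instead of half of it
    assert printed == pytest.approx(std - 0.25 * np.log(4.0), abs=1e-9)


@given(st.floats(-3, 3), st.floats(-3, 3), st.floats(0.2, 4), st.floats(0.2, 4))
@settings(max_examples=50, deadline=None)
def test_bhattacharyya_symmetric_nonnegative(m1, m2, v1, v2):
    a = bhattacharyya_from_moments([m1], [[v1]], [m2], [[v2]], ridge=0.0)
    b = bhattacharyya_from_moments([m2], [[v2]], [m1], [[v1]], ridge=0.0)
    assert a == pytest.approx(b, abs=1e-9)
    assert a >= -1e-12


def test_bhattacharyya_needs_enough_points():
    with pytest.raises(ValueError, match="more points than dimensions"):
        bhattacharyya_distance(np.zeros((2, 2)), np.zeros((5, 2)))


# --- reference scaling (Eq. 1)

def _two_batch_example():
    rows = [("B1_s1", "B1", 0.0, 1, "baseline"),
            ("B1_s2", "B1", 4.0, 1, "treated"),
            ("B2_s1", "B2", 0.0, 1, "baseline"),
            ("B2_s2", "B2", 4.0, 1, "treated")]
    meta = SampleMeta(pd.DataFrame(rows, columns=["sample_id", "batch",
                                                  "timepoint_days",
                                                  "replicate", "role"]))
    vals = pd.DataFrame([[1.0, 3.0, 3.0, 9.0]], index=["f1"],
                        columns=[r[0] for r in rows])
    return OmicsMatrix(vals, modality="metabolite", scale="raw"), meta


def test_batch_mean_scaling_worked_example():
    mat, meta = _two_batch_example()
    out = reference_scale_normalize(mat, meta, ReferenceScheme("batch_mean"))
    got = out.values.loc["f1"].to_numpy()
    assert got == pytest.approx([2.0, 6.0, 2.0, 6.0])


def test_reference_scaling_exact_for_multiplicative_factor():
    meta = make_meta(n_batches=3, timepoints=(0.0, 2.0, 4.0), n_replicates=2)
    clean = make_matrix(meta, n_features=8, seed=2)
    factors = {"B1": 1.0, "B2": 3.0, "B3": 0.25}
    scaled = clean.values.copy()
    batch_of = meta.table.set_index("sample_id")["batch"]
    for s in scaled.columns:
        scaled[s] = scaled[s] * factors[batch_of.loc[s]]
    corrupted = clean.copy_with(scaled)
    out = reference_scale_normalize(corrupted, meta,
                                    ReferenceScheme("batch_mean"))
    ref = reference_scale_normalize(clean, meta, ReferenceScheme("batch_mean"))
    # the batch factor cancels exactly; the grand averages R differ between
    # the corrupted and clean inputs, so agreement is up to one constant
    # per feature shared by all samples
    ratio = out.values.to_numpy() / ref.values.to_numpy()
    np.testing.assert_allclose(ratio / ratio[:, [0]], 1.0, rtol=1e-12)


def test_reference_scheme_missing_reference_errors():
    meta = make_meta(qc_per_batch=0)
    mat = make_matrix(meta, n_features=3)
    with pytest.raises(ValueError, match="no 'qc' reference"):
        reference_scale_normalize(mat, meta, ReferenceScheme("qc"))


# --- quantile

def test_quantile_normalize_oracle():
    df = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]},
                      index=["a", "b", "c"])
    out = quantile_normalize(OmicsMatrix(df, modality="gene", scale="raw"))
    np.testing.assert_allclose(out.values["s1"], [2.5, 3.5, 4.5])
    np.testing.assert_allclose(out.values["s2"], [2.5, 3.5, 4.5])


def test_quantile_normalize_equalises_distributions():
    meta = make_meta()
    mat = make_matrix(meta, n_features=20, seed=8)
    out = quantile_normalize(mat).values.to_numpy()
    ref = np.sort(out[:, 0])
    for j in range(1, out.shape[1]):
        np.testing.assert_allclose(np.sort(out[:, j]), ref, rtol=1e-9)


# --- empirical Bayes

def test_eb_single_batch_is_identity():
    meta = make_meta(n_batches=1, timepoints=(0.0, 2.0, 4.0), n_replicates=3)
    mat = log_transform(make_matrix(meta, n_features=10, seed=4))
    out = eb_location_scale_adjust(mat, meta)
    np.testing.assert_allclose(out.values.to_numpy(), mat.values.to_numpy(),
                               atol=1e-6)


def test_eb_removes_additive_log_batch_shift():
    meta = make_meta(n_batches=2, timepoints=(0.0, 2.0, 4.0), n_replicates=3)
    mat = log_transform(make_matrix(meta, n_features=30, seed=6))
    shifted = mat.values.copy()
    b2 = meta.select(batch="B2")
    shifted[b2] = shifted[b2] + 2.0
    out = eb_location_scale_adjust(mat.copy_with(shifted), meta)
    b1 = meta.select(batch="B1")
    sep = abs(out.values[b1].mean(axis=1) - out.values[b2].mean(axis=1))
    assert sep.mean() < 0.2  # >= 90% of the 2.0 log2 shift removed


def test_apply_method_unknown():
    meta = make_meta()
    mat = make_matrix(meta, n_features=3)
    with pytest.raises(ValueError, match="unknown batch-correction"):
        apply_method(mat, meta, "magic")


def test_benchmark_records_method_failure():
    meta = make_meta(qc_per_batch=0)  # qc scheme cannot run
    mat = make_matrix(meta, n_features=12, seed=9)
    report = benchmark_methods(mat, meta, methods=("qc", "batch_mean"))
    assert report.per_method["qc"].error
    assert not report.per_method["batch_mean"].error
    summary = report.summary()
    assert set(summary["method"]) == {"none", "qc", "batch_mean"}
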