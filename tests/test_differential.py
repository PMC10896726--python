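"""Differential calling: ANOVA, BH FDR, selection gates, ratios, collapsing."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from senmetflux.differential import (anova_per_feature, attach_q_values,
                                     bh_fdr, collapse_replicates_median,
                                     log_transform, low_expression_filter,
                                     sams_ratio_foldchange,
                                     select_differential)
from senmetflux.io_model import OmicsMatrix
from .conftest import make_matrix, make_meta


# --- BH FDR

def test_bh_oracle():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.04, 0.05]),
                               [0.04, 0.04, 0.05, 0.05])


def test_bh_hand_step_up():
    p = np.array([0.003, 0.5, 0.02, 0.9, 0.04])
    m = len(p)
    order = np.argsort(p)
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    expected = np.empty(m)
    expected[order] = np.minimum(q_sorted, 1.0)
    np.testing.assert_allclose(bh_fdr(p), expected)


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
@settings(max_examples=100, deadline=None)
def test_bh_properties(ps):
    q = bh_fdr(ps)
    assert np.all(q >= np.asarray(ps) - 1e-12)
    assert np.all((q >= 0) & (q <= 1))
    # order preservation: smaller p never gets a larger q
    pairs = sorted(zip(ps, q))
    qs = [b for _, b in pairs]
    assert all(qs[i] <= qs[i + 1] + 1e-12 for i in range(len(qs) - 1))


def test_bh_rejects_bad_input():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])
    with pytest.raises(ValueError):
        bh_fdr([0.5, np.nan])


# --- ANOVA

def test_anova_matches_scipy_per_feature():
    meta = make_meta(n_batches=1, timepoints=(0.0, 2.0, 4.0), n_replicates=3)
    mat = log_transform(make_matrix(meta, n_features=5, seed=7))
    results = anova_per_feature(mat, meta, "B1")
    for r in results:
        groups = [mat.values.loc[r.feature_id,
                                 meta.select(batch="B1", timepoint=t)]
                  for t in (0.0, 2.0, 4.0)]
        F, p = stats.f_oneway(*groups)
        assert r.F_statistic == pytest.approx(float(F))
        assert r.p_value == pytest.approx(float(p))


def test_anova_constant_feature_untestable():
    meta = make_meta(n_batches=1, timepoints=(0.0, 2.0), n_replicates=2)
    vals = pd.DataFrame([[5.0] * 4], index=["f1"], columns=meta.sample_ids)
    mat = OmicsMatrix(vals, modality="metabolite", scale="log")
    r = anova_per_feature(mat, meta, "B1")[0]
    assert r.F_statistic == 0.0 and r.p_value == 1.0


def test_anova_excludes_qc_and_single_replicate_groups():
    meta = make_meta(n_batches=1, timepoints=(0.0, 2.0, 4.0), n_replicates=2,
                     qc_per_batch=2)
    mat = log_transform(make_matrix(meta, n_features=3, seed=1))
    vals = mat.values.drop(columns=meta.select(batch="B1", timepoint=4.0)[1:])
    with pytest.warns(UserWarning, match="fewer than 2"):
        results = anova_per_feature(mat.copy_with(vals),
                                    meta.for_samples(vals.columns), "B1")
    assert len(results) == 3


def test_attach_q_values_within_batch():
    meta = make_meta(n_batches=2, timepoints=(0.0, 2.0), n_replicates=3)
    mat = log_transform(make_matrix(meta, n_features=6, seed=2))
    results = []
    for b in meta.batches:
        results.extend(anova_per_feature(mat, meta, b))
    attach_q_values(results)
    for b in meta.batches:
        sub = [r for r in results if r.batch_id == b]
        np.testing.assert_allclose([r.q_value for r in sub],
                                   bh_fdr([r.p_value for r in sub]))


# --- selection gates

def _mk_result(fid, q, fc):
    from senmetflux.differential import DifferentialResult
    r = DifferentialResult(feature_id=fid, batch_id="B1", F_statistic=1.0,
                           p_value=q, max_abs_log2fc=fc)
    r.q_value = q
    return r


def test_select_metabolites_q_only():
    results = [_mk_result("m1", 0.01, 0.0), _mk_result("m2", 0.2, 5.0)]
    assert select_differential(results, "metabolite") == {"m1"}


def test_select_genes_need_foldchange_gate():
    lo = np.log2(1.5) - 0.01
    hi = np.log2(1.5) + 0.01
    results = [_mk_result("g1", 0.01, lo), _mk_result("g2", 0.01, hi),
               _mk_result("g3", 0.2, hi)]
    assert select_differential(results, "gene") == {"g2"}
    # stricter reading: |log2FC| >= 1.5
    assert select_differential(results, "gene", fc_on_log2=True) == set()


# --- low-expression filter

def test_low_expression_filter_drops_bottom_fraction():
    meta = make_meta(n_batches=1, timepoints=(0.0, 2.0), n_replicates=1)
    vals = pd.DataFrame(
        {s: [1.0, 2.0, 3.0, 4.0, 5.0] for s in meta.sample_ids},
        index=[f"g{i}" for i in range(5)])
    mat = OmicsMatrix(vals, modality="gene", scale="log")
    out = low_expression_filter(mat, fraction=0.4)
    assert out.feature_ids == ["g2", "g3", "g4"]


def test_low_expression_filter_gene_only():
    meta = make_meta()
    with pytest.raises(ValueError, match="gene matrices"):
        low_expression_filter(make_matrix(meta, modality="metabolite"))


# --- replicate collapsing

def test_collapse_replicates_median():
    meta = make_meta(n_batches=2, timepoints=(0.0, 2.0), n_replicates=3,
                     qc_per_batch=1)
    mat = log_transform(make_matrix(meta, n_features=4, seed=3))
    collapsed, info = collapse_replicates_median(mat, meta)
    assert collapsed.shape == (4, 4)  # 2 batches x 2 timepoints, no QC
    ids = [s for s in meta.select(batch="B1", timepoint=2.0)
           if meta.identity(s)[2] != "qc"]
    expected = mat.values[ids].median(axis=1)
    np.testing.assert_allclose(collapsed.values["B1_d2"], expected)
    assert list(info["column"]) == list(collapsed.values.columns)


# --- SAMS ratios

def test_sams_ratio_worked_example():
    rows = [("B1_d0_r1", "B1", 0.0, 1, "baseline"),
            ("B1_d0_r2", "B1", 0.0, 2, "baseline"),
            ("B1_d8_r1", "B1", 8.0, 1, "treated"),
            ("B1_d8_r2", "B1", 8.0, 2, "treated")]
    from senmetflux.io_model import SampleMeta
    meta = SampleMeta(pd.DataFrame(rows, columns=["sample_id", "batch",
                                                  "timepoint_days",
                                                  "replicate", "role"]))
    vals = pd.DataFrame([[2.0, 2.0, 8.0, 8.0],     # numerator
                         [4.0, 4.0, 4.0, 4.0]],    # denominator
                        index=["A", "B"], columns=[r[0] for r in rows])
    mat = OmicsMatrix(vals, modality="metabolite", scale="raw")
    res = sams_ratio_foldchange(mat, meta, [("A", "B")], "B1")[0]
    # start ratio 0.5, end ratio 2.0 -> fold change 4
    assert res.fold_change == pytest.approx(4.0)
    assert res.per_replicate == pytest.approx([4.0, 4.0])
    assert np.isnan(res.p_value)  # zero variance across replicates


def test_sams_ratio_zero_denominator_flagged():
    meta = make_meta(n_batches=1, timepoints=(0.0, 8.0), n_replicates=2)
    vals = make_matrix(meta, n_features=2, seed=1).values
    nan_den = vals.copy()
    nan_den.loc["met001", meta.select(batch="B1", timepoint=0.0)] = np.nan
    mat = OmicsMatrix(nan_den, modality="metabolite", scale="raw")
    res = sams_ratio_foldchange(mat, meta, [("met000", "met001")], "B1")[0]
    assert np.isnan(res.fold_change)
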