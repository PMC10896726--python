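"""Per-batch differential calling and the metabolite-ratio shift signature.

The differential pipeline follows common time-course omics practice: log2
transform, one-way ANOVA across timepoint groups within each batch,
Benjamini-Hochberg FDR control, and threshold-based selection (metabolites:
q < 0.05; genes additionally require a 1.5-fold maximum change vs the start
of the course).  The ratio signature quantifies the senescence-associated
metabolic shift: for a metabolite pair (A, B) in one time course, the fold
change of A:B between the end and the start of the course, computed on
replicate means with a per-replicate two-sided t-test against 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import OmicsMatrix, SampleMeta

GENE_FC_THRESHOLD = 1.5  # fold-change gate for gene selection
Q_THRESHOLD = 0.05


@dataclass
class DifferentialResult:
    feature_id: str
    batch_id: str
    F_statistic: float
    p_value: float
    q_value: float = np.nan
    max_abs_log2fc: float = np.nan
    significant: bool = False


@dataclass
class RatioResult:
    numerator_id: str
    denominator_id: str
    batch_id: str
    fold_change: float
    start_timepoint: float
    end_timepoint: float
    per_replicate: list[float]
    p_value: float


def log_transform(matrix: OmicsMatrix) -> OmicsMatrix:
    """log2-transform a raw matrix (imputing missing values first)."""
    if matrix.scale != "raw":
        raise ValueError("matrix is already log scale")
    imputed = matrix.impute_missing()
    vals = imputed.values.to_numpy(dtype=float)
    if np.nanmin(vals) <= 0:
        raise ValueError("non-positive value remains after imputation")
    return matrix.copy_with(np.log2(imputed.values), scale="log")


def anova_per_feature(matrix: OmicsMatrix, meta: SampleMeta,
                      batch: str) -> list[DifferentialResult]:
    """One-way ANOVA across timepoint groups for every feature of one batch.

    Features whose within- and between-group variances both vanish (constant
    values) are untestable and reported with F = 0, p = 1.  Groups with
    fewer than two replicates are dropped; a feature needs at least two
    usable groups to be tested.
    """
    if matrix.scale != "log":
        raise ValueError("ANOVA expects a log-scale matrix")
    tps = meta.timepoints(batch)
    groups_cols = []
    for t in tps:
        ids = [s for s in meta.select(batch=batch, timepoint=t)
               if meta.identity(s)[2] != "qc"]
        if len(ids) >= 2:
            groups_cols.append(ids)
        else:
            warnings.warn(f"batch {batch} timepoint {t:g}: fewer than 2 "
                          "replicates, group excluded from ANOVA")
    if len(groups_cols) < 2:
        raise ValueError(f"batch {batch}: fewer than 2 timepoint groups with "
                         ">= 2 replicates")
    arrays = [matrix.values[cols].to_numpy(dtype=float) for cols in groups_cols]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant inputs raise scipy warnings
        F, p = stats.f_oneway(*arrays, axis=1)
    F = np.asarray(F, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(F) | ~np.isfinite(p)
    F[degenerate] = 0.0
    p[degenerate] = 1.0

    start_cols = groups_cols[0]
    start_mean = matrix.values[start_cols].mean(axis=1)
    max_fc = np.zeros(matrix.shape[0])
    for cols in groups_cols[1:]:
        fc = (matrix.values[cols].mean(axis=1) - start_mean).abs()
        max_fc = np.maximum(max_fc, fc.to_numpy())

    return [DifferentialResult(feature_id=fid, batch_id=batch,
                               F_statistic=float(F[i]), p_value=float(p[i]),
                               max_abs_log2fc=float(max_fc[i]))
            for i, fid in enumerate(matrix.feature_ids)]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving, q >= p)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attach_q_values(results: list[DifferentialResult]) -> list[DifferentialResult]:
    """Compute BH q-values within each batch and store them on the results."""
    df = pd.DataFrame([(r.batch_id, i, r.p_value) for i, r in enumerate(results)],
                      columns=["batch", "i", "p"])
    for _, grp in df.groupby("batch"):
        q = bh_fdr(grp["p"].to_numpy())
        for idx, qv in zip(grp["i"], q):
            results[idx].q_value = float(qv)
    return results


def select_differential(results: list[DifferentialResult], modality: str,
                        q_threshold: float = Q_THRESHOLD,
                        fc_threshold: float = GENE_FC_THRESHOLD,
                        fc_on_log2: bool = False) -> set[str]:
    """Features significant in at least one batch.

    Metabolites: q < 0.05.  Genes: q < 0.05 and a maximum absolute log2 fold
    change of at least log2(1.5) vs the start of the course (set
    ``fc_on_log2=True`` for the stricter |log2FC| >= 1.5 reading).
    """
    log2_gate = fc_threshold if fc_on_log2 else np.log2(fc_threshold)
    selected: set[str] = set()
    for r in results:
        ok = r.q_value < q_threshold
        if modality == "gene":
            ok = ok and r.max_abs_log2fc >= log2_gate
        r.significant = bool(ok)
        if ok:
            selected.add(r.feature_id)
    return selected


def low_expression_filter(matrix: OmicsMatrix, fraction: float = 0.4) -> OmicsMatrix:
    """Drop the bottom ``fraction`` of genes by mean expression over all samples.

    The number removed is floor(fraction * n); ties at the cut are resolved
    by feature-id lexicographic order so the result is deterministic.
    """
    if matrix.modality != "gene":
        raise ValueError("low-expression filter applies to gene matrices")
    n_remove = int(np.floor(fraction * matrix.shape[0]))
    means = matrix.values.mean(axis=1)
    order = means.to_frame("mean").assign(fid=means.index).sort_values(
        ["mean", "fid"], kind="mergesort")
    keep = sorted(order.index[n_remove:])
    return matrix.copy_with(matrix.values.loc[keep])


def collapse_replicates_median(matrix: OmicsMatrix, meta: SampleMeta,
                               include_qc: bool = False
                               ) -> tuple[OmicsMatrix, pd.DataFrame]:
    """One column per (batch, timepoint), the median over replicates.

    Returns the collapsed matrix and a small metadata table with the batch
    and timepoint of every collapsed column.
    """
    t = meta.table
    if not include_qc:
        t = t[t["role"] != "qc"]
    cols, rows = {}, []
    for (b, tp), grp in t.groupby(["batch", "timepoint_days"], sort=True):
        ids = [s for s in grp["sample_id"] if s in matrix.values.columns]
        if not ids:
            continue
        name = f"{b}_d{tp:g}"
        cols[name] = matrix.values[ids].median(axis=1)
        rows.append((name, b, float(tp)))
    collapsed = matrix.copy_with(pd.DataFrame(cols))
    info = pd.DataFrame(rows, columns=["column", "batch", "timepoint_days"])
    return collapsed, info


def sams_ratio_foldchange(matrix: OmicsMatrix, meta: SampleMeta,
                          pairs: list[tuple[str, str]], batch: str,
                          reference_timepoint: float | None = None
                          ) -> list[RatioResult]:
    """End-vs-start fold change of metabolite ratios for one time course.

    For a pair (numerator A, denominator B) the statistic is
    (A_end/B_end) / (A_start/B_start) on replicate means; per-replicate
    ratios feed a two-sided one-sample t-test of the end/start ratio vs 1.
    ``reference_timepoint`` overrides the course start as the proliferative
    reference (used when the earliest sampled day is not a proliferative
    state).  Requires raw-scale levels.
    """
    if matrix.scale != "raw":
        raise ValueError("ratio fold changes are computed on raw-scale levels")
    tps = meta.timepoints(batch)
    start = float(reference_timepoint) if reference_timepoint is not None else tps[0]
    end = tps[-1]
    if start not in tps:
        raise ValueError(f"reference timepoint {start:g} not sampled in {batch}")
    start_ids = [s for s in meta.select(batch=batch, timepoint=start)
                 if meta.identity(s)[2] != "qc"]
    end_ids = [s for s in meta.select(batch=batch, timepoint=end)
               if meta.identity(s)[2] != "qc"]
    out: list[RatioResult] = []
    for num, den in pairs:
        levels = matrix.values.loc[[num, den]]
        s_num, s_den = levels.loc[num, start_ids], levels.loc[den, start_ids]
        e_num, e_den = levels.loc[num, end_ids], levels.loc[den, end_ids]
        if (s_den.isna() | (s_den == 0)).all() or (e_den.isna() | (e_den == 0)).all():
            out.append(RatioResult(num, den, batch, np.nan, start, end, [], np.nan))
            continue
        fc = float((e_num.mean() / e_den.mean()) / (s_num.mean() / s_den.mean()))
        start_ratio = float(s_num.mean() / s_den.mean())
        per_rep = [float((en / ed) / start_ratio)
                   for en, ed in zip(e_num, e_den) if ed and np.isfinite(en / ed)]
        if len(per_rep) >= 2 and np.std(per_rep, ddof=1) > 0:
            p = float(stats.ttest_1samp(per_rep, popmean=1.0).pvalue)
        else:
            p = np.nan
        out.append(RatioResult(num, den, batch, fc, start, end, per_rep, p))
    return out
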