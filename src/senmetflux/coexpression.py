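"""Weighted-correlation-network module detection for temporal profiles.

Implements the classic weighted coexpression workflow on median-collapsed
time profiles: soft-threshold power selection against a scale-free topology
fit, unsigned topological overlap (TOM) similarity, average-linkage
hierarchical clustering of the TOM dissimilarity with a simplified dynamic
height cut, module eigenprofiles (first principal component of the member
profiles) and eigenprofile-correlation-based module merging.  Also provides
the integrated trajectory PCA used to visualise metabolome dynamics across
batches after correction.

The full published dynamic hybrid tree cut is deliberately not re-implemented;
``deepSplit`` maps to the cut-height fraction of a plain height cut (the
mapping is documented on :func:`cluster_modules`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io_model import OmicsMatrix, SampleMeta

#: deepSplit -> fraction of the linkage-height range at which the tree is cut
DEEPSPLIT_CUT_FRACTION = {0: 0.95, 1: 0.90, 2: 0.85, 3: 0.80, 4: 0.75}


@dataclass
class SoftThresholdScan:
    powers: list[int]
    r_squared: list[float]
    mean_connectivity: list[float]
    chosen: int


@dataclass
class ModuleParams:
    min_size: int = 3
    deep_split: int = 3
    merge_threshold: float = 0.60
    power: int = 6
    merge_on_dissimilarity: bool = True  # merge when 1 - cor < threshold

    def validate(self) -> None:
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.deep_split not in DEEPSPLIT_CUT_FRACTION:
            raise ValueError("deep_split must be in 0..4")
        if not 0 < self.merge_threshold < 1:
            raise ValueError("merge_threshold must be in (0, 1)")
        if self.power < 1:
            raise ValueError("power must be >= 1")

    @property
    def merge_cor_cutoff(self) -> float:
        """Eigenprofile correlation above which two modules are merged."""
        return (1.0 - self.merge_threshold if self.merge_on_dissimilarity
                else self.merge_threshold)


@dataclass
class ModuleSet:
    labels: pd.Series                      # feature -> module label (0 = none)
    eigenprofiles: dict[int, np.ndarray]   # module -> score vector over samples
    explained_variance: dict[int, float]
    merge_history: list[tuple[int, int]] = field(default_factory=list)
    params: ModuleParams | None = None

    @property
    def modules(self) -> list[int]:
        return sorted(m for m in self.labels.unique() if m != 0)

    def members(self, module: int) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def sizes(self) -> dict[int, int]:
        return {m: int((self.labels == m).sum()) for m in self.modules}


def _abs_correlation(profiles: np.ndarray) -> np.ndarray:
    """|Pearson| between profile rows; zero-variance rows correlate at 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(profiles)
    cor = np.abs(np.nan_to_num(cor, nan=0.0))
    cor = np.clip(cor, 0.0, 1.0)
    np.fill_diagonal(cor, 1.0)
    return cor


def _scale_free_r2(k: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log connectivity-distribution fit, 10 bins.

    A scale-free network has a *decreasing* log-log degree distribution, so
    the fit quality is signed by the regression slope: a positive slope
    yields a negative value, marking the topology as not scale-free however
    well the line fits.
    """
    k = k[k > 0]
    if k.size < 3 or np.allclose(k, k[0]):
        return np.nan
    edges = np.exp(np.linspace(np.log(k.min()), np.log(k.max()) + 1e-12,
                               n_bins + 1))
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = which == b
        if sel.sum() > 0:
            xs.append(np.log10(k[sel].mean()))
            ys.append(np.log10(sel.mean()))
    if len(xs) < 3:
        return np.nan
    x, y = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot <= 0:
        return np.nan
    r2 = float(1 - resid @ resid / ss_tot)
    return -r2 if slope > 0 else r2


def _default_power(n_samples: int) -> int:
    """Fallback adjacency power by sample count (unsigned network)."""
    if n_samples < 20:
        return 9
    if n_samples < 30:
        return 8
    if n_samples < 40:
        return 7
    return 6


def pick_soft_threshold(profiles: pd.DataFrame,
                        powers: range = range(1, 21),
                        r2_cut: float = 0.8) -> SoftThresholdScan:
    """Choose the adjacency power: lowest with signed scale-free R^2 >= 0.8.

    If no power reaches the cut — common for small feature sets whose
    degree distribution is nothing like scale-free — the fallback is the
    conventional sample-count default power for unsigned networks rather
    than chasing the maximum of a noisy fit curve.
    """
    if profiles.shape[0] < 10:
        raise ValueError("soft-threshold selection needs >= 10 features")
    cor = _abs_correlation(profiles.to_numpy(dtype=float))
    r2s, conns = [], []
    for beta in powers:
        adj = cor ** beta
        np.fill_diagonal(adj, 0.0)
        k = adj.sum(axis=1)
        conns.append(float(k.mean()))
        r2s.append(_scale_free_r2(k))
    r2_arr = np.asarray(r2s, dtype=float)
    candidates = [p for p, r2 in zip(powers, r2_arr)
                  if np.isfinite(r2) and r2 >= r2_cut]
    if candidates:
        chosen = candidates[0]
    else:
        chosen = _default_power(profiles.shape[1])
        warnings.warn("no power reaches the scale-free fit cut; using the "
                      f"sample-count default power {chosen}")
    return SoftThresholdScan(powers=list(powers), r_squared=list(r2_arr),
                             mean_connectivity=conns, chosen=int(chosen))


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Unsigned topological overlap of a [0,1] adjacency with unit diagonal.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), the sum
    excluding u in {i, j}, with k the off-diagonal row sum; TOM_ii = 1.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if A.min() < -1e-12 or A.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(A), 1.0):
        raise ValueError("adjacency must have unit diagonal")
    k = A.sum(axis=1) - 1.0
    shared = A @ A - 2.0 * A  # removes u = i and u = j terms (unit diagonal)
    denom = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (shared + A) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def module_eigenprofile(profiles: pd.DataFrame, members: list[str]
                        ) -> tuple[np.ndarray, float]:
    """First principal-component score vector of the standardized members.

    Returns (eigenprofile over samples, fraction of variance explained);
    the sign is oriented to correlate positively with the member mean.
    """
    if not members:
        raise ValueError("eigenprofile of an empty member list")
    X = profiles.loc[members].to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = Vt[0]
    total = (S ** 2).sum()
    explained = float(S[0] ** 2 / total) if total > 0 else 0.0
    mean_profile = Z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return eig, explained


def cluster_modules(profiles: pd.DataFrame, params: ModuleParams) -> ModuleSet:
    """Detect coexpression modules on median-collapsed profiles.

    Average-linkage clustering of 1 - TOM; the tree is cut at a height
    fraction mapped from ``deep_split`` (0..4 -> 0.95..0.75 of the linkage
    range, deeper splits cutting lower), clusters below ``min_size`` are
    unassigned (label 0), and modules whose eigenprofiles correlate above
    the merge cutoff are merged iteratively until none do.
    """
    params.validate()
    fids = list(profiles.index)
    n = len(fids)
    cor = _abs_correlation(profiles.to_numpy(dtype=float))
    adj = np.clip(cor ** params.power, 0.0, 1.0)
    np.fill_diagonal(adj, 1.0)
    dissim = 1.0 - tom_similarity(adj)
    np.fill_diagonal(dissim, 0.0)
    dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
    if n < 2:
        labels = pd.Series(0, index=fids)
        return ModuleSet(labels=labels, eigenprofiles={}, explained_variance={},
                         params=params)
    Z = hierarchy.average(squareform(dissim, checks=False))
    heights = Z[:, 2]
    hmin, hmax = float(heights.min()), float(heights.max())
    frac = DEEPSPLIT_CUT_FRACTION[params.deep_split]
    cut = hmin + frac * (hmax - hmin) if hmax > hmin else hmax
    raw = hierarchy.fcluster(Z, t=cut, criterion="distance")

    # enforce minimum size, relabel surviving modules by decreasing size
    sizes = pd.Series(raw).value_counts()
    keep = [int(c) for c in sizes.index if sizes[c] >= params.min_size]
    keep.sort(key=lambda c: (-sizes[c], c))
    remap = {c: i + 1 for i, c in enumerate(keep)}
    labels = pd.Series([remap.get(int(c), 0) for c in raw], index=fids)

    module_set = ModuleSet(labels=labels, eigenprofiles={},
                           explained_variance={}, params=params)
    _recompute_eigenprofiles(module_set, profiles)
    _merge_modules(module_set, profiles)
    return module_set


def _recompute_eigenprofiles(ms: ModuleSet, profiles: pd.DataFrame) -> None:
    ms.eigenprofiles, ms.explained_variance = {}, {}
    for m in ms.modules:
        eig, ev = module_eigenprofile(profiles, ms.members(m))
        ms.eigenprofiles[m] = eig
        ms.explained_variance[m] = ev


def _merge_modules(ms: ModuleSet, profiles: pd.DataFrame) -> None:
    cutoff = ms.params.merge_cor_cutoff
    while True:
        mods = ms.modules
        if len(mods) < 2:
            break
        best, best_cor = None, cutoff
        for i, m1 in enumerate(mods):
            for m2 in mods[i + 1:]:
                c = float(np.corrcoef(ms.eigenprofiles[m1],
                                      ms.eigenprofiles[m2])[0, 1])
                if c > best_cor:
                    best, best_cor = (m1, m2), c
        if best is None:
            break
        m1, m2 = best
        ms.labels[ms.labels == m2] = m1
        ms.merge_history.append((m2, m1))
        _recompute_eigenprofiles(ms, profiles)
    # post-merge invariant: no remaining pair correlates above the cutoff
    mods = ms.modules
    for i, m1 in enumerate(mods):
        for m2 in mods[i + 1:]:
            c = float(np.corrcoef(ms.eigenprofiles[m1],
                                  ms.eigenprofiles[m2])[0, 1])
            assert c <= cutoff + 1e-9, "module merge invariant violated"


# ---------------------------------------------------------------------------
# integrated trajectory PCA

@dataclass
class TrajectoryPCA:
    scores: pd.DataFrame            # samples x components
    pct_variance: np.ndarray        # per component, sums to 100
    correlation_circle: pd.DataFrame  # features x first two components
    trajectories: dict[str, pd.DataFrame]  # batch -> ordered median scores


def trajectory_pca(matrix: OmicsMatrix, meta: SampleMeta,
                   scale_features: bool = True) -> TrajectoryPCA:
    """Centered (optionally unit-scaled) PCA of samples over features.

    Returns per-component % variance (summing to 100 over all components),
    the correlation-circle coordinates (correlation of every feature with
    the first two component scores) and, per batch, the temporal trajectory
    of median-collapsed sample scores.
    """
    vals = matrix.values
    if vals.isna().any().any():
        raise ValueError("trajectory PCA requires a complete matrix; impute "
                         "missing values upstream")
    X = vals.to_numpy(dtype=float).T  # samples x features
    X = X - X.mean(axis=0)
    if scale_features:
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        X = X / sd
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    scores = U * S
    var = S ** 2
    pct = 100.0 * var / var.sum()
    comp_names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    scores_df = pd.DataFrame(scores, index=vals.columns, columns=comp_names)

    circle = {}
    for comp in comp_names[:2]:
        s = scores_df[comp].to_numpy()
        cors = []
        for i in range(vals.shape[0]):
            f = vals.iloc[i].to_numpy(dtype=float)
            c = np.corrcoef(f, s)[0, 1] if f.std() > 0 and s.std() > 0 else 0.0
            cors.append(c)
        circle[comp] = cors
    circle_df = pd.DataFrame(circle, index=vals.index)

    trajectories: dict[str, pd.DataFrame] = {}
    t = meta.table[meta.table["role"] != "qc"]
    for batch, grp in t.groupby("batch"):
        rows = []
        for tp, sub in grp.groupby("timepoint_days"):
            ids = [s for s in sub["sample_id"] if s in scores_df.index]
            if ids:
                rows.append((float(tp), *scores_df.loc[ids].median(axis=0)))
        tr = pd.DataFrame(rows, columns=["timepoint_days", *comp_names])
        trajectories[batch] = tr.sort_values("timepoint_days").reset_index(drop=True)
    return TrajectoryPCA(scores=scores_df, pct_variance=pct,
                         correlation_circle=circle_df, trajectories=trajectories)
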