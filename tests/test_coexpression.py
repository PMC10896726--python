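"""Module detection: TOM oracle, soft threshold, clustering, merging, PCA."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from senmetflux.coexpression import (ModuleParams, cluster_modules,
                                     module_eigenprofile, pick_soft_threshold,
                                     tom_similarity, trajectory_pca)
from senmetflux.differential import log_transform
from .conftest import make_matrix, make_meta


def brute_force_tom(A):
    n = A.shape[0]
    k = A.sum(axis=1) - 1.0
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n)
                         if u != i and u != j)
            T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


def _random_adjacency(rng, n):
    cor = rng.uniform(0, 1, size=(n, n))
    A = (cor + cor.T) / 2
    np.fill_diagonal(A, 1.0)
    return A


def test_tom_matches_brute_force():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = rng.integers(3, 9)
        A = _random_adjacency(rng, n)
        np.testing.assert_allclose(tom_similarity(A), brute_force_tom(A),
                                   atol=1e-10)


def test_tom_validates_input():
    with pytest.raises(ValueError, match="symmetric"):
        tom_similarity(np.array([[1.0, 0.2], [0.5, 1.0]]))
    bad_diag = np.array([[0.5, 0.2], [0.2, 0.5]])
    with pytest.raises(ValueError, match="unit diagonal"):
        tom_similarity(bad_diag)


@given(arrays(np.float64, (5, 5), elements=st.floats(0.0, 1.0)))
@settings(max_examples=50, deadline=None)
def test_tom_bounded_and_symmetric(raw):
    A = (raw + raw.T) / 2
    np.fill_diagonal(A, 1.0)
    T = tom_similarity(A)
    assert T.min() >= 0.0 and T.max() <= 1.0
    np.testing.assert_allclose(T, T.T, atol=1e-10)
    np.testing.assert_allclose(np.diag(T), 1.0)


def _block_profiles(n_modules=4, per_module=8, n_samples=24, noise=0.05,
                    seed=0):
    rng = np.random.default_rng(seed)
    rows, names = [], []
    # orthogonalized base profiles so no two blocks correlate by chance
    raw = rng.normal(size=(n_samples, n_modules))
    base = np.linalg.qr(raw - raw.mean(axis=0))[0].T * np.sqrt(n_samples)
    for m in range(n_modules):
        for i in range(per_module):
            rows.append(base[m] + noise * rng.normal(size=n_samples))
            names.append(f"f{m}_{i}")
    return pd.DataFrame(rows, index=names)


def test_pick_soft_threshold_reports_scan():
    prof = _block_profiles()
    scan = pick_soft_threshold(prof)
    assert scan.chosen in scan.powers
    assert len(scan.r_squared) == len(scan.powers)
    # mean connectivity decreases with the power
    assert all(np.diff(scan.mean_connectivity) <= 1e-9)


def test_pick_soft_threshold_fallback_by_sample_count():
    # near-identical profiles: no power gives a scale-free (decreasing) fit
    rng = np.random.default_rng(1)
    base = rng.normal(size=24)
    prof = pd.DataFrame([base + 1e-3 * rng.normal(size=24) for _ in range(12)],
                        index=[f"f{i}" for i in range(12)])
    with pytest.warns(UserWarning, match="default power"):
        scan = pick_soft_threshold(prof)
    assert scan.chosen == 8  # 24 samples -> conventional unsigned default


def test_cluster_modules_recovers_blocks():
    prof = _block_profiles(n_modules=4, per_module=8, noise=0.05)
    ms = cluster_modules(prof, ModuleParams(min_size=3, deep_split=3,
                                            merge_threshold=0.60, power=6))
    assert len(ms.modules) == 4
    for m in ms.modules:
        prefixes = {f.split("_")[0] for f in ms.members(m)}
        assert len(prefixes) == 1  # no block is split across modules


def test_cluster_modules_min_size_unassigned():
    prof = _block_profiles(n_modules=2, per_module=8)
    rng = np.random.default_rng(5)
    lonely = pd.DataFrame([rng.normal(size=prof.shape[1])], index=["solo"])
    ms = cluster_modules(pd.concat([prof, lonely]),
                         ModuleParams(min_size=3, power=6))
    assert ms.labels["solo"] == 0


def test_merge_invariant_no_pair_above_cutoff():
    prof = _block_profiles(n_modules=5, per_module=6, noise=0.2, seed=3)
    params = ModuleParams(min_size=3, deep_split=4, merge_threshold=0.60,
                          power=6)
    ms = cluster_modules(prof, params)
    mods = ms.modules
    for i, m1 in enumerate(mods):
        for m2 in mods[i + 1:]:
            c = np.corrcoef(ms.eigenprofiles[m1], ms.eigenprofiles[m2])[0, 1]
            assert c <= params.merge_cor_cutoff + 1e-9


def test_module_eigenprofile_sign_and_variance():
    prof = _block_profiles(n_modules=1, per_module=10, noise=0.01)
    eig, ev = module_eigenprofile(prof, list(prof.index))
    assert ev > 0.95
    Z = (prof - prof.mean(axis=1).values[:, None])
    Z = Z / Z.std(axis=1).values[:, None]
    assert np.corrcoef(eig, Z.mean(axis=0))[0, 1] > 0


def test_params_validation():
    with pytest.raises(ValueError, match="deep_split"):
        ModuleParams(deep_split=7).validate()
    with pytest.raises(ValueError, match="merge_threshold"):
        ModuleParams(merge_threshold=1.5).validate()


def test_trajectory_pca_variance_and_trajectories():
    meta = make_meta(n_batches=2, timepoints=(0.0, 2.0, 4.0), n_replicates=2)
    mat = log_transform(make_matrix(meta, n_features=10, seed=4))
    pca = trajectory_pca(mat, meta)
    assert pca.pct_variance.sum() == pytest.approx(100.0)
    assert set(pca.trajectories) == {"B1", "B2"}
    tr = pca.trajectories["B1"]
    assert list(tr["timepoint_days"]) == [0.0, 2.0, 4.0]
    assert pca.correlation_circle.to_numpy().max() <= 1.0 + 1e-9
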