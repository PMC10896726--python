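"""Shared fixtures: small hand-built studies and the cached default study."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from senmetflux.io_model import OmicsMatrix, SampleMeta
from senmetflux.synthetic import SyntheticConfig, generate_study, \
    inject_batch_effects


def make_meta(n_batches=2, timepoints=(0.0, 2.0, 4.0), n_replicates=2,
              qc_per_batch=0):
    """A minimal metadata table; day-0 samples get the 'baseline' role."""
    rows = []
    for b in range(n_batches):
        batch = f"B{b + 1}"
        for t in timepoints:
            role = "baseline" if t == timepoints[0] else "treated"
            for r in range(1, n_replicates + 1):
                rows.append((f"{batch}_d{t:g}_r{r}", batch, float(t), r, role))
        for q in range(1, qc_per_batch + 1):
            rows.append((f"{batch}_qc{q}", batch, 0.0, q, "qc"))
    return SampleMeta(pd.DataFrame(rows, columns=["sample_id", "batch",
                                                  "timepoint_days",
                                                  "replicate", "role"]))


def make_matrix(meta: SampleMeta, n_features=6, seed=0, modality="metabolite",
                scale="raw"):
    rng = np.random.default_rng(seed)
    vals = rng.lognormal(mean=3.0, sigma=0.3,
                         size=(n_features, len(meta.sample_ids)))
    if scale == "log":
        vals = np.log2(vals)
    prefix = "met" if modality == "metabolite" else "g"
    df = pd.DataFrame(vals, index=[f"{prefix}{i:03d}" for i in range(n_features)],
                      columns=meta.sample_ids)
    return OmicsMatrix(df, modality=modality, scale=scale)


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (seed 42) with batch effects injected."""
    cfg = SyntheticConfig(seed=42)
    met, gen, meta, truth = generate_study(cfg)
    met = inject_batch_effects(met, truth, meta)
    gen = inject_batch_effects(gen, truth, meta)
    return met, gen, meta, truth


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for pipeline-level tests (fewer genes, same design)."""
    cfg = SyntheticConfig(seed=11, n_genes=120)
    met, gen, meta, truth = generate_study(cfg)
    met = inject_batch_effects(met, truth, meta)
    gen = inject_batch_effects(gen, truth, meta)
    return met, gen, meta, truth
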