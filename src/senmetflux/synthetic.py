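"""Synthetic multi-batch, multi-time-point senescence study generator.

Emulates the design of a time-resolved senescence multi-omics experiment:
several independent time courses ("batches", one per senescence inducer),
each sampled at a shared grid of days with a few biological replicates,
measuring a metabolome (~10^2 features) and a transcriptome (~10^2-10^3
features) on the same cells.

The generative model works on the log2 scale and exponentiates at the end so
raw intensities are strictly positive, like mass-spec peak areas:

    log2 X[f, (b,t,r)] = base_f + load_f * A[m(f),b] * shape_m(u_t) + eps

* every feature belongs to one latent module m (label 0 = unassigned noise);
* ``shape_m`` is one of four named temporal primitives (linear, logistic,
  transient, flat), centred and scaled to unit standard deviation over the
  time grid, with module-specific parameters;
* ``A[m,b]`` is the module amplitude in batch b: a fixed module sign and
  magnitude jittered per batch (a multiplicative scale-type batch effect);
* ``eps`` is i.i.d. Gaussian replicate noise.

Hub metabolites get a dedicated module shared with their partner genes, so
their trajectories correlate perfectly with every partner in every batch at
zero noise.  Module shapes are drawn with rejection sampling so distinct
modules are mutually decorrelated (planted structure is well separated by
construction).  Location-type batch effects are per-(feature, batch)
multiplicative log-normal factors, recorded in the ground truth and applied
by :func:`inject_batch_effects`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import (OmicsMatrix, SampleMeta, read_matrix, read_meta,
                       write_matrix, write_meta)

INDUCERS = ("RAS_OIS", "RAF_OIS", "DDIS", "RS", "QUI", "B6", "B7", "B8")

SHAPES = ("linear", "logistic", "transient", "biphasic", "flat")


class ConfigurationError(ValueError):
    """Raised for inconsistent synthetic-study configurations."""


@dataclass(frozen=True)
class HubSpec:
    """A planted hub: metabolite index, partner-gene count, target |rho|."""

    metabolite_index: int
    n_partner_genes: int
    target_abs_correlation: float = 0.5


@dataclass
class SyntheticConfig:
    """Study design and noise model for :func:`generate_study`.

    Defaults mirror the emulated experimental design: four inducer batches,
    six sampling days, three biological replicates, ~60 metabolites and ~500
    genes organised in five temporal modules per modality, two planted hub
    metabolites with 30 partner genes each, log-normal multiplicative batch
    effects and modest replicate noise on the log2 scale.
    """

    n_batches: int = 4
    timepoints: Sequence[float] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    n_replicates: int = 3
    n_metabolites: int = 60
    n_genes: int = 500
    n_modules: int = 5
    trajectory_shapes: Sequence[str] = ("linear", "logistic", "transient",
                                        "biphasic")
    hub_spec: Sequence[HubSpec] = (HubSpec(0, 30), HubSpec(1, 30))
    sigma_loc: float = 2.0     # log-scale sd of multiplicative batch factors
    sigma_scale: float = 0.15  # log-scale sd of per-batch module-amplitude jitter
    noise_sd: float = 0.2      # replicate noise sd, log2 scale
    qc_fraction: float = 0.15  # QC samples per batch, as fraction of its samples
    noise_feature_fraction: float = 0.1  # fraction of unassigned (flat) features
    module_amplitude: float = 1.5        # module trajectory sd, log2 units
    module_separation: float = 0.3       # max |cor| allowed between module shapes
    seed: int = 42

    def validate(self) -> None:
        counts = dict(n_batches=self.n_batches, n_replicates=self.n_replicates,
                      n_metabolites=self.n_metabolites, n_genes=self.n_genes,
                      n_modules=self.n_modules)
        for name, v in counts.items():
            if v < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {v}")
        if len(self.timepoints) < 2:
            raise ConfigurationError("need at least 2 timepoints")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not 0 <= self.qc_fraction < 1:
            raise ConfigurationError("qc_fraction must be in [0, 1)")
        unknown = set(self.trajectory_shapes) - set(SHAPES)
        if unknown:
            raise ConfigurationError(f"unknown trajectory shapes {sorted(unknown)}")
        for hub in self.hub_spec:
            if not 0 <= hub.metabolite_index < self.n_metabolites:
                raise ConfigurationError(
                    f"hub metabolite index {hub.metabolite_index} out of range")
            if hub.n_partner_genes > self.n_genes:
                raise ConfigurationError(
                    "hub partner count exceeds number of genes")
        if self.n_batches > len(INDUCERS):
            raise ConfigurationError(f"at most {len(INDUCERS)} batches supported")


@dataclass
class GroundTruth:
    """Planted structure: module labels, hubs, batch factors, latent profiles."""

    module_label: dict[str, int]
    hub_features: list[str]
    hub_partners: dict[str, list[str]]
    batch_factor: pd.DataFrame      # features x batches, strictly positive
    baseline_profile: pd.DataFrame  # features x timepoints, log2 latent (batch 1)
    timepoints: list[float]

    def metabolite_labels(self, feature_ids: Sequence[str]) -> np.ndarray:
        return np.array([self.module_label[f] for f in feature_ids])


def default_config(**overrides) -> SyntheticConfig:
    """The default study conditions used throughout the test battery."""
    return SyntheticConfig(**overrides)


# ---------------------------------------------------------------------------
# trajectory primitives

def _shape_curve(shape: str, params: dict[str, float], u: np.ndarray) -> np.ndarray:
    if shape == "linear":
        y = params.get("slope", 1.0) * u
    elif shape == "logistic":
        y = 1.0 / (1.0 + np.exp(-params["steepness"] * (u - params["midpoint"])))
    elif shape == "transient":
        y = np.exp(-0.5 * ((u - params["peak"]) / params["width"]) ** 2)
    elif shape == "biphasic":
        y = np.sin(2.0 * np.pi * (params["cycle_span"] * u + params["phase"]))
    elif shape == "flat":
        return np.zeros_like(u)
    else:  # pragma: no cover - guarded by config validation
        raise ConfigurationError(f"unknown shape {shape!r}")
    y = y - y.mean()
    sd = y.std()
    return y / sd if sd > 0 else y


def _draw_shape(rng: np.random.Generator, shapes: Sequence[str],
                u: np.ndarray, start_band: tuple[float, float] = (-1.7, -0.4),
                max_tries: int = 50) -> np.ndarray:
    """One random standardized trajectory that departs from a low start.

    Trajectories model responses unfolding from a resting state, so the
    day-0 value of every (non-flat) curve is constrained below the curve's
    mean.  Callers narrow ``start_band`` further to pin all batch
    realisations of one module to a shared day-0 level, which keeps day-0
    (and, via exact centring, pooled-QC) reference samples comparable
    across batches.  Rejection-sampled; the last draw is kept if the
    constraint cannot be met (flat shapes are exempt).
    """
    lo, hi = start_band
    for _ in range(max_tries):
        shape = shapes[rng.integers(len(shapes))]
        params = {
            "slope": 1.0,
            "steepness": rng.uniform(6.0, 14.0),
            "midpoint": rng.uniform(0.25, 0.75),
            "peak": rng.uniform(0.15, 0.85),
            "width": rng.uniform(0.12, 0.30),
            "phase": rng.uniform(0.55, 0.95),
            "cycle_span": rng.uniform(0.8, 1.1),
        }
        y = _shape_curve(shape, params, u)
        if shape == "flat" or lo <= y[0] <= hi:
            return y
    return y


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=-1, keepdims=True)
    sd = X.std(axis=-1, keepdims=True)
    return np.where(sd > 0, (X - mu) / np.where(sd == 0, 1, sd), 0.0)


def _stack_stats(stack: np.ndarray, rng: np.random.Generator,
                 rel_noise: float, n_jitter: int = 64
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Noise-perturbed standardized per-batch ranks, plus the standardized
    concatenation of the clean stack.

    Shapes with plateaus (logistic tails, transient shoulders) have
    near-tied values whose clean rank order is knife-edge: under replicate
    noise the realised Spearman correlation can sit far from the
    zero-noise value.  The separation criterion therefore scores rank
    agreement on ``n_jitter`` noise realisations at the generator's own
    effective noise level rather than on the clean curves alone.
    """
    jittered = stack[None, :, :] + rng.normal(
        0.0, max(rel_noise, 1e-12), size=(n_jitter,) + stack.shape)
    ranks = np.argsort(np.argsort(jittered, axis=-1), axis=-1).astype(float)
    return _standardize_rows(ranks), _standardize_rows(stack.ravel())


def _pair_needs(kind_a: str, kind_b: str) -> tuple[bool, bool]:
    """Which separation criteria a module-kind pair must satisfy.

    Returns (edge_criterion, strict_concat).  The edge criterion applies
    whenever the pair can put a gene and a metabolite feature on the two
    ends of a network edge: metabolite-vs-gene modules, and every pair
    involving a hub module (hubs carry a metabolite *and* partner genes).
    The strict concatenated-correlation criterion applies to pairs of
    metabolite modules, which must stay apart in the metabolome clustering
    and eigenprofile merging.
    """
    kinds = {kind_a, kind_b}
    edge = "hub" in kinds or kinds == {"met", "gene"}
    strict_concat = kinds == {"met"}
    return edge, strict_concat


def _separation_violation(cand_stats, other_stats, edge: bool,
                          strict_concat: bool, separation: float,
                          loose_concat: float, edge_level: float,
                          edge_leak_tol: float) -> float:
    """How badly two module stacks violate their separation criteria.

    Concatenation criterion: the |Pearson| of the clean concatenated
    profiles must stay below ``separation`` for metabolite-module pairs
    (clustering / eigenprofile merging) and below ``loose_concat``
    otherwise.  Edge criterion: the probability that a random member pair
    exceeds the network threshold ``edge_level`` in *every* batch —
    estimated as the product over batches of the smoothed fraction of
    noise-perturbed rank profiles with |rho| > edge_level — must stay
    below ``edge_leak_tol``, so only planted hub pairings survive the
    all-batches overlap.  Returns the maximum criterion ratio; < 1 means
    separated.
    """
    (zr_a, zc_a), (zr_b, zc_b) = cand_stats, other_stats
    t = zr_a.shape[-1]
    concat = float(abs((zc_a * zc_b).mean()))
    limit = separation if strict_concat else loose_concat
    score = concat / limit
    if edge:
        rho = np.abs((zr_a * zr_b).sum(axis=-1) / t)   # n_jitter x n_batches
        k = rho.shape[0]
        p = (np.count_nonzero(rho > edge_level, axis=0) + 1.0) / (k + 2.0)
        log_leak = float(np.log(p).sum())
        # ratio < 1 iff leak probability < tolerance
        score = max(score, np.log(edge_leak_tol) / min(log_leak, -1e-12))
    return score


def _draw_separated_shapes(rng: np.random.Generator, kinds: Sequence[str],
                           shapes: Sequence[str], u: np.ndarray,
                           n_batches: int, separation: float,
                           rel_noise: float = 0.08,
                           loose_concat: float = 0.65,
                           edge_level: float = 0.5,
                           edge_leak_tol: float = 2e-3,
                           max_tries: int = 400,
                           max_refine: int = 6000) -> list[np.ndarray]:
    """Draw per-batch shape stacks for the modules described by ``kinds``.

    ``kinds`` holds one of {"met", "gene", "hub"} per module; the pairwise
    criteria follow from :func:`_pair_needs`.  Each module's per-batch
    shapes are drawn independently and rejection-sampled against the
    accepted modules; a greedy single-batch refinement pass then fixes
    residual violations.  If the budget runs out the best configuration
    seen is kept, so the procedure always terminates (and stays
    deterministic under a fixed generator).
    """
    non_flat = [s for s in shapes if s != "flat"] or list(shapes)
    n = len(kinds)
    # Pin each module's day-0 shape value to a module-specific narrow band
    # so that all batch realisations of a module start at the same level
    # (stable day-0 references across batches), while different modules
    # keep distinct start levels (separable concatenated profiles).  Band
    # centres span the whole standardized range; the module's random
    # amplitude sign decides whether features rise or fall from there.
    bands = [(c - 0.12, c + 0.12)
             for c in rng.uniform(-1.45, 1.05, size=n)]
    accepted: list[np.ndarray] = []
    accepted_stats: list[tuple[np.ndarray, np.ndarray]] = []

    def _viol(i: int, j: int) -> float:
        edge, strict_concat = _pair_needs(kinds[i], kinds[j])
        return _separation_violation(accepted_stats[i], accepted_stats[j],
                                     edge=edge, strict_concat=strict_concat,
                                     separation=separation,
                                     loose_concat=loose_concat,
                                     edge_level=edge_level,
                                     edge_leak_tol=edge_leak_tol)

    for i in range(n):
        best, best_stats, best_score = None, None, np.inf
        for _try in range(max_tries):
            cand = np.stack([_draw_shape(rng, non_flat, u, bands[i])
                             for _ in range(n_batches)])
            cand_stats = _stack_stats(cand, rng, rel_noise)
            accepted_stats.append(cand_stats)
            score = max((_viol(i, j) for j in range(i)), default=0.0)
            accepted_stats.pop()
            if score < best_score:
                best, best_stats, best_score = cand, cand_stats, score
            if score < 1.0:
                break
        accepted.append(best)
        accepted_stats.append(best_stats)

    # Refinement: whole-stack rejection stalls because a violating pair only
    # needs *one* discordant batch; greedily resample single batch rows of
    # the worst-separated module until every pair satisfies its criteria.
    viol = np.zeros((n, n))
    for i in range(n):
        for j in range(i):
            viol[i, j] = viol[j, i] = _viol(i, j)
    for _step in range(max_refine):
        worst = float(viol.max())
        if worst < 1.0:
            break
        i, j = np.unravel_index(int(viol.argmax()), viol.shape)
        # modify whichever of the pair is worse off overall (tie: later one)
        target = i if (viol[i].max(), i) >= (viol[j].max(), j) else j
        b = int(rng.integers(n_batches))
        old_row = accepted[target][b].copy()
        old_stats = accepted_stats[target]
        accepted[target][b] = _draw_shape(rng, non_flat, u, bands[target])
        accepted_stats[target] = _stack_stats(accepted[target], rng, rel_noise)
        new_viol = np.array([_viol(target, k) if k != target else 0.0
                             for k in range(n)])
        if new_viol.max() < viol[target].max():
            viol[target, :] = new_viol
            viol[:, target] = new_viol
        else:
            accepted[target][b] = old_row
            accepted_stats[target] = old_stats
    return accepted


# ---------------------------------------------------------------------------
# study generation

def _sample_layout(config: SyntheticConfig) -> pd.DataFrame:
    """Deterministic sample table: batches x timepoints x replicates (+ QC)."""
    rows = []
    batches = INDUCERS[: config.n_batches]
    n_qc = int(round(config.qc_fraction * len(config.timepoints) * config.n_replicates))
    for b in batches:
        for t in config.timepoints:
            for r in range(1, config.n_replicates + 1):
                role = "baseline" if t == min(config.timepoints) else "treated"
                rows.append((f"{b}_d{t:g}_r{r}", b, float(t), r, role))
        for r in range(1, n_qc + 1):
            rows.append((f"{b}_qc{r}", b, float(min(config.timepoints)), r, "qc"))
    return pd.DataFrame(rows, columns=["sample_id", "batch", "timepoint_days",
                                       "replicate", "role"])


def generate_study(config: SyntheticConfig
                   ) -> tuple[OmicsMatrix, OmicsMatrix, SampleMeta, GroundTruth]:
    """Generate (metabolome, transcriptome, meta, truth) for one synthetic study.

    The returned matrices are clean of location-type batch effects; apply
    :func:`inject_batch_effects` with the returned truth to add them.
    Identical config and seed give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    tp = np.asarray(config.timepoints, dtype=float)
    u = (tp - tp.min()) / (tp.max() - tp.min())
    batches = list(INDUCERS[: config.n_batches])
    layout = _sample_layout(config)
    meta = SampleMeta(layout.copy())

    met_ids = [f"met{i:03d}" for i in range(config.n_metabolites)]
    gene_ids = [f"gene{i:04d}" for i in range(config.n_genes)]

    # --- module bookkeeping -------------------------------------------------
    n_hub = len(config.hub_spec)
    # module ids: 1..M metabolite modules, M+1..2M gene modules, then hub modules
    met_mods = list(range(1, config.n_modules + 1))
    gene_mods = list(range(config.n_modules + 1, 2 * config.n_modules + 1))
    hub_mods = list(range(2 * config.n_modules + 1, 2 * config.n_modules + 1 + n_hub))
    all_mods = met_mods + gene_mods + hub_mods

    # Metabolite modules must stay apart in the metabolome clustering; any
    # pair that can bridge the two molecular layers (met-gene, and every
    # hub pairing) must additionally keep its all-batches network-edge
    # leak probability negligible.
    draw_order = met_mods + hub_mods + gene_mods
    kinds = (["met"] * len(met_mods) + ["hub"] * len(hub_mods)
             + ["gene"] * len(gene_mods))
    # effective noise on a replicate-median profile point, in shape units
    rel_noise = (config.noise_sd
                 / (np.sqrt(config.n_replicates) * config.module_amplitude))
    stacks = _draw_separated_shapes(rng, kinds,
                                    config.trajectory_shapes, u,
                                    config.n_batches,
                                    config.module_separation,
                                    rel_noise=rel_noise)
    # shape per (module, batch): each time course realises the module anew
    shape_of = {(m, b): stacks[i][k]
                for i, m in enumerate(draw_order) for k, b in enumerate(batches)}
    sign_of = {m: (1.0 if rng.random() < 0.5 else -1.0) for m in all_mods}
    # per-(module, batch) amplitude: fixed sign, jittered magnitude
    amp = {
        (m, b): sign_of[m] * config.module_amplitude
                * np.exp(rng.normal(0.0, config.sigma_scale))
        for m in all_mods for b in batches
    }

    # --- feature -> module assignment --------------------------------------
    module_label: dict[str, int] = {}

    def _assign(ids: list[str], mods: list[int]) -> None:
        n_noise = int(round(config.noise_feature_fraction * len(ids)))
        assignable = ids[: len(ids) - n_noise]
        for k, fid in enumerate(assignable):
            module_label[fid] = mods[k % len(mods)]
        for fid in ids[len(ids) - n_noise:]:
            module_label[fid] = 0

    _assign(met_ids, met_mods)
    _assign(gene_ids, gene_mods)

    hub_features: list[str] = []
    hub_partners: dict[str, list[str]] = {}
    next_gene = config.n_genes  # allocate partner genes from the list tail
    for hub, hub_mod in zip(config.hub_spec, hub_mods):
        hid = met_ids[hub.metabolite_index]
        module_label[hid] = hub_mod
        partners = gene_ids[next_gene - hub.n_partner_genes: next_gene]
        next_gene -= hub.n_partner_genes
        if next_gene < 0:
            raise ConfigurationError("hub partner genes exceed gene count")
        for g in partners:
            module_label[g] = hub_mod
        hub_features.append(hid)
        hub_partners[hid] = list(partners)

    feature_ids = met_ids + gene_ids
    base = dict(zip(feature_ids, rng.uniform(8.0, 16.0, size=len(feature_ids))))
    load = dict(zip(feature_ids, rng.uniform(0.7, 1.3, size=len(feature_ids))))

    # --- latent log2 profiles per (feature, batch, timepoint) ---------------
    def latent(fid: str, b: str) -> np.ndarray:
        m = module_label[fid]
        if m == 0:
            return np.full(len(tp), base[fid])
        return base[fid] + load[fid] * amp[(m, b)] * shape_of[(m, b)]

    sample_ids = list(layout["sample_id"])
    log2_vals = {"metabolite": np.zeros((len(met_ids), len(sample_ids))),
                 "gene": np.zeros((len(gene_ids), len(sample_ids)))}
    ids_of = {"metabolite": met_ids, "gene": gene_ids}

    # precompute per-(feature,batch) latent curves and per-batch pooled means
    lat = {(fid, b): latent(fid, b) for fid in feature_ids for b in batches}

    col_meta = layout.set_index("sample_id")
    for modality in ("metabolite", "gene"):
        fids = ids_of[modality]
        for j, sid in enumerate(sample_ids):
            row = col_meta.loc[sid]
            b = row["batch"]
            if row["role"] == "qc":
                mean_prof = np.array([lat[(fid, b)].mean() for fid in fids])
                clean = mean_prof
            else:
                ti = int(np.argmin(np.abs(tp - float(row["timepoint_days"]))))
                clean = np.array([lat[(fid, b)][ti] for fid in fids])
            noise = (rng.normal(0.0, config.noise_sd, size=len(fids))
                     if config.noise_sd > 0 else 0.0)
            log2_vals[modality][:, j] = clean + noise

    metabolome = OmicsMatrix(
        pd.DataFrame(np.exp2(log2_vals["metabolite"]), index=met_ids,
                     columns=sample_ids),
        modality="metabolite", scale="raw")
    transcriptome = OmicsMatrix(
        pd.DataFrame(np.exp2(log2_vals["gene"]), index=gene_ids,
                     columns=sample_ids),
        modality="gene", scale="raw")

    factors = pd.DataFrame(
        np.exp(rng.normal(0.0, config.sigma_loc, size=(len(feature_ids), len(batches)))),
        index=feature_ids, columns=batches)

    baseline_profile = pd.DataFrame(
        np.array([lat[(fid, batches[0])] for fid in feature_ids]),
        index=feature_ids, columns=[f"{t:g}" for t in tp])

    truth = GroundTruth(module_label=module_label, hub_features=hub_features,
                        hub_partners=hub_partners, batch_factor=factors,
                        baseline_profile=baseline_profile,
                        timepoints=[float(t) for t in tp])
    return metabolome, transcriptome, meta, truth


def inject_batch_effects(matrix: OmicsMatrix, truth: GroundTruth,
                         meta: SampleMeta) -> OmicsMatrix:
    """Multiply every entry by its (feature, batch) factor from the truth."""
    if matrix.scale != "raw":
        raise ValueError("batch factors are multiplicative on raw intensities")
    missing = [f for f in matrix.feature_ids if f not in truth.batch_factor.index]
    if missing:
        raise ValueError(f"no batch factor recorded for features: {missing[:5]}")
    if (truth.batch_factor.to_numpy() <= 0).any():
        raise ValueError("batch factors must be strictly positive")
    vals = matrix.values.copy()
    sample_batch = meta.table.set_index("sample_id")["batch"]
    for sid in vals.columns:
        b = sample_batch.loc[sid]
        vals[sid] = vals[sid] * truth.batch_factor.loc[vals.index, b].to_numpy()
    return matrix.copy_with(vals)


# ---------------------------------------------------------------------------
# persistence

def write_study(metabolome: OmicsMatrix, transcriptome: OmicsMatrix,
                meta: SampleMeta, truth: GroundTruth,
                directory: str | Path) -> dict[str, Path]:
    """Write metabolome.tsv, transcriptome.tsv, samples.tsv and truth.json."""
    if not str(directory).strip():
        raise ValueError("empty output directory path")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "metabolome": directory / "metabolome.tsv",
        "transcriptome": directory / "transcriptome.tsv",
        "samples": directory / "samples.tsv",
        "truth": directory / "truth.json",
    }
    write_matrix(metabolome, paths["metabolome"])
    write_matrix(transcriptome, paths["transcriptome"])
    write_meta(meta, paths["samples"])
    blob = {
        "module_label": truth.module_label,
        "hub_features": truth.hub_features,
        "hub_partners": truth.hub_partners,
        "batch_factor": {f: {b: float(truth.batch_factor.loc[f, b])
                             for b in truth.batch_factor.columns}
                         for f in truth.batch_factor.index},
        "baseline_profile": {f: [float(x) for x in truth.baseline_profile.loc[f]]
                             for f in truth.baseline_profile.index},
        "timepoints": truth.timepoints,
    }
    paths["truth"].write_text(json.dumps(blob, indent=1))
    return paths


def read_study(directory: str | Path
               ) -> tuple[OmicsMatrix, OmicsMatrix, SampleMeta, GroundTruth]:
    directory = Path(directory)
    metabolome = read_matrix(directory / "metabolome.tsv", modality="metabolite")
    transcriptome = read_matrix(directory / "transcriptome.tsv", modality="gene")
    meta = read_meta(directory / "samples.tsv")
    blob = json.loads((directory / "truth.json").read_text())
    features = list(blob["batch_factor"])
    batches = list(next(iter(blob["batch_factor"].values())))
    factors = pd.DataFrame(
        [[blob["batch_factor"][f][b] for b in batches] for f in features],
        index=features, columns=batches)
    baseline = pd.DataFrame(
        [blob["baseline_profile"][f] for f in features], index=features,
        columns=[f"{t:g}" for t in blob["timepoints"]])
    truth = GroundTruth(
        module_label={k: int(v) for k, v in blob["module_label"].items()},
        hub_features=list(blob["hub_features"]),
        hub_partners={k: list(v) for k, v in blob["hub_partners"].items()},
        batch_factor=factors, baseline_profile=baseline,
        timepoints=[float(t) for t in blob["timepoints"]])
    return metabolome, transcriptome, meta, truth
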