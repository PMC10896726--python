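"""End-to-end pipeline: generate/ingest -> differential -> batch benchmark ->
modules -> integration network -> enrichment -> report.

Every stage writes plain TSV/JSON outputs into the run directory and records
inputs, parameters and content hashes in ``manifest.json``, so a run with an
identical configuration reproduces identical files.  Stages can be toggled
off; downstream stages that depend on a disabled stage are skipped.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .batch_correction import (ALL_METHODS, apply_method, benchmark_methods)
from .coexpression import ModuleParams, cluster_modules, pick_soft_threshold, \
    trajectory_pca
from .differential import (anova_per_feature, attach_q_values,
                           collapse_replicates_median, log_transform,
                           low_expression_filter, sams_ratio_foldchange,
                           select_differential)
from .enrichment import gsea_collection, hypergeometric_ora, \
    rank_genes_by_foldchange
from .integration import (build_network, overlap_select, rank_hubs,
                          spearman_pairs, write_network)
from .io_model import (OmicsMatrix, SampleMeta, align, read_gmt, read_matrix,
                       read_meta, write_matrix)
from .synthetic import SyntheticConfig, generate_study, inject_batch_effects, \
    write_study


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``synthetic`` holds generator settings (keys of
    :class:`~senmetflux.synthetic.SyntheticConfig`) or the three input paths
    point at existing TSV files.  Parameter defaults are the study's:
    q < 0.05, gene fold-change gate 1.5x, |rho| > 0.5 in every dataset,
    module minimum sizes 3 (metabolites) / 100 (genes), deepSplit 3, merge
    threshold 0.60, bottom-40% expression filter.
    """

    out_dir: str = "run"
    seed: int = 42
    synthetic: dict[str, Any] | None = field(default_factory=dict)
    metabolome_path: str | None = None
    transcriptome_path: str | None = None
    meta_path: str | None = None
    gmt_path: str | None = None
    ratio_pairs: list[tuple[str, str]] = field(default_factory=list)
    stages: dict[str, bool] = field(default_factory=dict)
    q_threshold: float = 0.05
    gene_fc_threshold: float = 1.5
    correlation_threshold: float = 0.5
    low_expression_fraction: float = 0.4
    met_min_size: int = 3
    gene_min_size: int = 100
    deep_split: int = 3
    merge_threshold: float = 0.60
    n_permutations: int = 1000
    top_k_hubs: int = 20
    correction_method: str = "batch_mean"

    STAGE_NAMES = ("simulate", "differential", "batchbench", "modules",
                   "integrate", "enrich", "report")

    def enabled(self, stage: str) -> bool:
        return self.stages.get(stage, True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        blob = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**blob)
        for p in (cfg.metabolome_path, cfg.transcriptome_path, cfg.meta_path,
                  cfg.gmt_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: RunConfig, out: Path):
    if config.metabolome_path:
        if not (config.transcriptome_path and config.meta_path):
            raise PipelineError("simulate", "file inputs need metabolome, "
                                            "transcriptome and metadata paths")
        for p in (config.metabolome_path, config.transcriptome_path,
                  config.meta_path):
            if not Path(p).exists():
                raise PipelineError("simulate", f"missing input file {p}")
        met = read_matrix(config.metabolome_path, modality="metabolite")
        gen = read_matrix(config.transcriptome_path, modality="gene")
        meta = read_meta(config.meta_path)
        truth = None
    else:
        syn = dict(config.synthetic or {})
        syn.setdefault("seed", config.seed)
        scfg = SyntheticConfig(**syn)
        met, gen, meta, truth = generate_study(scfg)
        met = inject_batch_effects(met, truth, meta)
        gen = inject_batch_effects(gen, truth, meta)
        write_study(met, gen, meta, truth, out / "input")
    align(met, meta)
    align(gen, meta)
    return met, gen, meta, truth


def run_pipeline(config: RunConfig) -> Path:
    """Execute all enabled stages in dependency order; returns the run dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__, "seed": config.seed,
        "parameters": {k: v for k, v in asdict(config).items()
                       if k not in ("stages",)},
        "stages_run": [], "outputs": {},
    }

    def record(stage: str, *paths: Path) -> None:
        manifest["stages_run"].append(stage)
        for p in paths:
            if p.exists():
                manifest["outputs"][str(p.relative_to(out))] = _sha256(p)

    try:
        met_raw, gen_raw, meta, truth = _load_inputs(config, out)
        record("simulate")

        # All downstream analysis runs on batch-corrected intensities; the
        # benchmark stage below still scores every method on the raw data.
        met_cor = apply_method(met_raw, meta, config.correction_method)
        gen_cor = apply_method(gen_raw, meta, config.correction_method)
        met_log = log_transform(met_cor)
        gen_log = log_transform(gen_cor)
        gen_log = low_expression_filter(gen_log, config.low_expression_fraction)

        diff_sets: dict[str, set[str]] = {}
        if config.enabled("differential"):
            for name, mat in (("metabolite", met_log), ("gene", gen_log)):
                results = []
                for b in meta.batches:
                    results.extend(anova_per_feature(mat, meta, b))
                attach_q_values(results)
                diff_sets[name] = select_differential(
                    results, name, q_threshold=config.q_threshold,
                    fc_threshold=config.gene_fc_threshold)
                pd.DataFrame([asdict_result(r) for r in results]).to_csv(
                    out / f"differential_{name}.tsv", sep="\t", index=False)
            if config.ratio_pairs:
                rows = []
                for b in meta.batches:
                    for r in sams_ratio_foldchange(met_raw, meta,
                                                   config.ratio_pairs, b):
                        rows.append((r.numerator_id, r.denominator_id,
                                     r.batch_id, r.fold_change,
                                     r.start_timepoint, r.end_timepoint,
                                     r.p_value))
                pd.DataFrame(rows, columns=["numerator", "denominator",
                                            "batch", "fold_change", "start",
                                            "end", "p_value"]).to_csv(
                    out / "sams_ratios.tsv", sep="\t", index=False)
            record("differential", out / "differential_metabolite.tsv",
                   out / "differential_gene.tsv", out / "sams_ratios.tsv")

        if config.enabled("batchbench"):
            report = benchmark_methods(met_raw, meta)
            report.summary().to_csv(out / "batch_benchmark.tsv", sep="\t",
                                    index=False)
            record("batchbench", out / "batch_benchmark.tsv")

        modules = None
        if config.enabled("modules"):
            collapsed, _ = collapse_replicates_median(met_log, meta)
            scan = pick_soft_threshold(collapsed.values)
            params = ModuleParams(min_size=config.met_min_size,
                                  deep_split=config.deep_split,
                                  merge_threshold=config.merge_threshold,
                                  power=scan.chosen)
            modules = cluster_modules(collapsed.values, params)
            mod_df = modules.labels.rename("module").to_frame()
            mod_df.index.name = "feature_id"
            mod_df.to_csv(out / "metabolite_modules.tsv", sep="\t")
            corrected = apply_method(met_raw, meta, "eb")
            pca = trajectory_pca(log_transform(corrected), meta)
            pd.DataFrame({"component": [f"PC{i+1}" for i in
                                        range(len(pca.pct_variance))],
                          "pct_variance": pca.pct_variance}).to_csv(
                out / "pca_variance.tsv", sep="\t", index=False)
            record("modules", out / "metabolite_modules.tsv",
                   out / "pca_variance.tsv")

        network = None
        if config.enabled("integrate") and config.enabled("differential"):
            genes_d = gen_log.copy_with(
                gen_log.values.loc[sorted(diff_sets.get("gene", set()))])
            mets_d = met_log.copy_with(
                met_log.values.loc[sorted(diff_sets.get("metabolite", set()))])
            if genes_d.shape[0] and mets_d.shape[0]:
                tables = [spearman_pairs(genes_d, mets_d, meta, b)
                          for b in meta.batches]
                pairs = overlap_select(tables, config.correlation_threshold)
                if not pairs.empty:
                    network = build_network(pairs)
                    write_network(network, pairs, out / "network")
                    rank_hubs(network, top_k=config.top_k_hubs).to_csv(
                        out / "network" / "top_hubs.tsv", sep="\t", index=False)
            record("integrate", out / "network" / "nodes.tsv",
                   out / "network" / "top_hubs.tsv")

        if config.enabled("enrich") and config.gmt_path:
            collection = read_gmt(config.gmt_path)
            universe = set(gen_log.feature_ids)
            rows = []
            for b in meta.batches:
                ranking = rank_genes_by_foldchange(gen_log, meta, b)
                for res in gsea_collection(ranking, collection,
                                           n_perm=config.n_permutations,
                                           seed=config.seed):
                    rows.append((b, res.set_id, res.es, res.nes, res.p_value))
            pd.DataFrame(rows, columns=["dataset", "set_id", "es", "nes",
                                        "p_value"]).to_csv(
                out / "gsea.tsv", sep="\t", index=False)
            query = diff_sets.get("gene", set())
            ora = hypergeometric_ora(query, collection, universe)
            pd.DataFrame([(r.set_id, r.annotated, r.overlap, r.p_value,
                           r.q_value) for r in ora],
                         columns=["set_id", "annotated", "overlap", "p",
                                  "q"]).to_csv(out / "ora.tsv", sep="\t",
                                               index=False)
            record("enrich", out / "gsea.tsv", out / "ora.tsv")

        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
        if config.enabled("report"):
            make_report(out)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        (failed / "error.txt").write_text(str(exc))
        stage = manifest["stages_run"][-1] if manifest["stages_run"] else "setup"
        raise PipelineError(stage, str(exc)) from exc
    return out


def asdict_result(r) -> dict[str, Any]:
    return {"feature_id": r.feature_id, "batch_id": r.batch_id,
            "F": r.F_statistic, "p": r.p_value, "q": r.q_value,
            "max_abs_log2fc": r.max_abs_log2fc, "significant": r.significant}


def make_report(run_dir: str | Path) -> Path:
    """Plain-text summary of a (possibly partial) completed run."""
    run_dir = Path(run_dir)
    lines = ["senmetflux run summary", "=" * 30]
    gaps = []

    diff = run_dir / "differential_metabolite.tsv"
    if diff.exists():
        df = pd.read_csv(diff, sep="\t")
        counts = df[df["significant"]].groupby("batch_id")["feature_id"].nunique()
        lines.append("\nDifferential metabolites per batch:")
        if counts.empty:
            lines.append("  none (downstream network sections skipped)")
        for b, c in counts.items():
            lines.append(f"  {b}: {c}")
    else:
        gaps.append("differential")

    ratios = run_dir / "sams_ratios.tsv"
    if ratios.exists():
        df = pd.read_csv(ratios, sep="\t")
        lines.append("\nMetabolite-ratio fold changes (end vs start):")
        for _, r in df.iterrows():
            lines.append(f"  {r['numerator']}:{r['denominator']} "
                         f"[{r['batch']}] = {r['fold_change']:.2f} "
                         f"(p = {r['p_value']:.3g})")

    bench = run_dir / "batch_benchmark.tsv"
    if bench.exists():
        df = pd.read_csv(bench, sep="\t")
        lines.append("\nBatch-correction benchmark (median r.s.d. | median "
                     "repeatability | mean between-batch DB):")
        for _, r in df.iterrows():
            lines.append(f"  {r['method']:<11} {r['median_rsd']:.3f} | "
                         f"{r['median_repeatability']:.3f} | "
                         f"{r['mean_between_batch_db']:.3f}")
    else:
        gaps.append("batchbench")

    mods = run_dir / "metabolite_modules.tsv"
    if mods.exists():
        df = pd.read_csv(mods, sep="\t")
        sizes = df[df["module"] != 0]["module"].value_counts().sort_index()
        lines.append(f"\nMetabolite modules: {len(sizes)} "
                     f"(sizes {[int(v) for v in sizes.values]}; "
                     f"{int((df['module'] == 0).sum())} unassigned)")
    else:
        gaps.append("modules")

    hubs = run_dir / "network" / "top_hubs.tsv"
    if hubs.exists():
        df = pd.read_csv(hubs, sep="\t")
        lines.append("\nTop network hubs by betweenness:")
        for _, r in df.head(20).iterrows():
            lines.append(f"  #{int(r['rank']):>2} {r['node']:<12} "
                         f"({r['kind']}, degree {int(r['degree'])}, "
                         f"betweenness {r['betweenness']:.1f})")
    else:
        gaps.append("integrate")

    if gaps:
        lines.append("\nSections without outputs (disabled or failed): "
                     + ", ".join(gaps))
    text = "\n".join(lines) + "\n"
    path = run_dir / "report.txt"
    path.write_text(text)
    return path
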