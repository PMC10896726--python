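"""Transcriptome-metabolome integration: correlation network and hub ranking.

For every (differential) gene x metabolite pair and every dataset (batch),
the Spearman correlation of the two median-collapsed time profiles is
computed.  Pairs whose absolute correlation exceeds a threshold in *every*
dataset are joined into an undirected bipartite gene-metabolite graph, on
which exact (Brandes) betweenness centrality identifies hub molecules: the
nodes mediating the most shortest-path traffic between the two molecular
layers, irrespective of the senescence inducer.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .differential import collapse_replicates_median
from .io_model import OmicsMatrix, SampleMeta


@dataclass
class CorrelationTable:
    """Per-dataset Spearman rho for every gene-metabolite pair."""

    dataset_id: str
    table: pd.DataFrame  # columns: gene_id, metabolite_id, spearman_rho, n_points


def _rankdata_rows(X: np.ndarray) -> np.ndarray:
    """Average ranks along rows (tie-aware), vectorised."""
    from scipy.stats import rankdata
    return np.apply_along_axis(rankdata, 1, X)


def spearman_pairs(genes: OmicsMatrix, metabolites: OmicsMatrix,
                   meta: SampleMeta, dataset: str) -> CorrelationTable:
    """Spearman rho between every gene and metabolite profile in one dataset.

    Profiles are median-collapsed over replicates per timepoint; at least
    four shared timepoints are required for the correlation to be
    meaningful.  Ties are handled by average ranking.
    """
    sub_meta_rows = meta.table[(meta.table["batch"] == dataset)
                               & (meta.table["role"] != "qc")]
    sub = SampleMeta(sub_meta_rows.copy())
    g_ids = [s for s in sub.sample_ids if s in genes.values.columns]
    m_ids = [s for s in sub.sample_ids if s in metabolites.values.columns]
    g_mat, g_info = collapse_replicates_median(
        genes.copy_with(genes.values[g_ids]), sub.for_samples(g_ids))
    m_mat, m_info = collapse_replicates_median(
        metabolites.copy_with(metabolites.values[m_ids]), sub.for_samples(m_ids))
    shared = [c for c in g_info["column"] if c in set(m_info["column"])]
    if len(shared) < 4:
        raise ValueError(f"dataset {dataset!r}: fewer than 4 shared timepoints")
    G = g_mat.values[shared].to_numpy(dtype=float)
    M = m_mat.values[shared].to_numpy(dtype=float)

    Rg = _rankdata_rows(G)
    Rm = _rankdata_rows(M)

    def _standardize(R: np.ndarray) -> np.ndarray:
        mu = R.mean(axis=1, keepdims=True)
        sd = R.std(axis=1, keepdims=True)
        Z = np.where(sd > 0, (R - mu) / np.where(sd == 0, 1, sd), 0.0)
        return Z

    Zg, Zm = _standardize(Rg), _standardize(Rm)
    rho = (Zg @ Zm.T) / len(shared)  # genes x metabolites
    rho = np.clip(rho, -1.0, 1.0)

    gi, mi = np.meshgrid(np.arange(len(g_mat.feature_ids)),
                         np.arange(len(m_mat.feature_ids)), indexing="ij")
    table = pd.DataFrame({
        "gene_id": np.asarray(g_mat.feature_ids)[gi.ravel()],
        "metabolite_id": np.asarray(m_mat.feature_ids)[mi.ravel()],
        "spearman_rho": rho.ravel(),
        "n_points": len(shared),
    })
    return CorrelationTable(dataset_id=dataset, table=table)


def overlap_select(tables: list[CorrelationTable],
                   threshold: float = 0.5) -> pd.DataFrame:
    """Pairs with |rho| > threshold in every dataset.

    Sign consistency across datasets is not required; pairs missing from
    any dataset are excluded.  Returns one row per selected pair with the
    per-dataset rho values as extra columns.
    """
    if not tables:
        raise ValueError("no correlation tables supplied")
    merged = None
    for t in tables:
        cols = t.table[["gene_id", "metabolite_id", "spearman_rho"]].rename(
            columns={"spearman_rho": f"rho_{t.dataset_id}"})
        merged = cols if merged is None else merged.merge(
            cols, on=["gene_id", "metabolite_id"], how="inner")
    rho_cols = [c for c in merged.columns if c.startswith("rho_")]
    mask = (merged[rho_cols].abs() > threshold).all(axis=1)
    return merged[mask].reset_index(drop=True)


def build_network(pairs: pd.DataFrame) -> nx.Graph:
    """Undirected, unweighted bipartite graph from selected pairs."""
    if pairs.empty:
        raise ValueError("empty pair set")
    g = nx.Graph()
    for _, row in pairs.iterrows():
        g.add_node(row["gene_id"], kind="gene")
        g.add_node(row["metabolite_id"], kind="metabolite")
        g.add_edge(row["gene_id"], row["metabolite_id"])
    return g


def betweenness_centrality(graph: nx.Graph,
                           normalized: bool = False) -> dict[str, float]:
    """Exact betweenness on the undirected unweighted graph.

    Raw values count each unordered node pair once; ``normalized=True``
    divides by (n-1)(n-2)/2.  Disconnected graphs are fine (contributions
    accumulate within components).
    """
    if graph.number_of_nodes() < 3:
        raise ValueError("betweenness needs at least 3 nodes")
    return nx.betweenness_centrality(graph, normalized=normalized)


def rank_hubs(graph: nx.Graph, top_k: int = 20,
              kind: str | None = None) -> pd.DataFrame:
    """Nodes sorted by descending betweenness (ties: degree, then id).

    ``kind`` restricts the ranking to "gene" or "metabolite" nodes.  If
    ``top_k`` exceeds the node count the full ranking is returned.
    """
    bc = betweenness_centrality(graph, normalized=False)
    n = graph.number_of_nodes()
    norm = (n - 1) * (n - 2) / 2.0
    rows = []
    for node, val in bc.items():
        node_kind = graph.nodes[node].get("kind", "unknown")
        if kind is not None and node_kind != kind:
            continue
        rows.append((node, node_kind, graph.degree[node], val,
                     val / norm if norm > 0 else np.nan))
    df = pd.DataFrame(rows, columns=["node", "kind", "degree", "betweenness",
                                     "betweenness_normalized"])
    df = df.sort_values(["betweenness", "degree", "node"],
                        ascending=[False, False, True],
                        kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.head(top_k) if top_k < len(df) else df


def correlated_gene_sets(tables: list[CorrelationTable], metabolite: str,
                         sign: str, threshold: float = 0.5,
                         min_datasets: int = 3) -> list[str]:
    """Genes correlating with one metabolite, with the requested sign,
    above |threshold| in at least ``min_datasets`` datasets."""
    if sign not in ("positive", "negative"):
        raise ValueError("sign must be 'positive' or 'negative'")
    counts: dict[str, int] = {}
    seen_metabolite = False
    for t in tables:
        sub = t.table[t.table["metabolite_id"] == metabolite]
        if not sub.empty:
            seen_metabolite = True
        rho = sub["spearman_rho"]
        ok = (rho > threshold) if sign == "positive" else (rho < -threshold)
        for g in sub.loc[ok, "gene_id"]:
            counts[g] = counts.get(g, 0) + 1
    if not seen_metabolite:
        raise ValueError(f"unknown metabolite {metabolite!r}")
    return sorted(g for g, c in counts.items() if c >= min_datasets)


def write_network(graph: nx.Graph, pairs: pd.DataFrame, out_dir) -> None:
    """Write the pair table, a SIF-compatible edge list and node attributes."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs.to_csv(out / "pairs.tsv", sep="\t", index=False)
    with open(out / "edges.sif", "w", encoding="utf-8") as fh:
        for a, b in sorted(graph.edges()):
            fh.write(f"{a} pp {b}\n")
    rank_hubs(graph, top_k=graph.number_of_nodes()).to_csv(
        out / "nodes.tsv", sep="\t", index=False)
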