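"""Integration network: Spearman cross-check, overlap rule, betweenness, hubs."""
import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from senmetflux.integration import (CorrelationTable, betweenness_centrality,
                                    build_network, correlated_gene_sets,
                                    overlap_select, rank_hubs, spearman_pairs,
                                    write_network)
from senmetflux.differential import log_transform
from .conftest import make_matrix, make_meta


def brute_force_betweenness(graph):
    """Path-enumeration betweenness: count shortest paths via BFS per pair."""
    nodes = list(graph.nodes)
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        n_paths = len(paths)
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / n_paths
    return bc


def test_betweenness_matches_brute_force_random_graphs():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(3, 13))
        p = float(rng.uniform(0.2, 0.8))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(1 << 31)))
        if g.number_of_nodes() < 3:
            continue
        got = betweenness_centrality(g, normalized=False)
        expected = brute_force_betweenness(g)
        for v in g.nodes:
            assert got[v] == pytest.approx(expected[v], abs=1e-9)


def test_betweenness_needs_three_nodes():
    g = nx.Graph([("a", "b")])
    with pytest.raises(ValueError, match="at least 3"):
        betweenness_centrality(g)


def test_spearman_pairs_matches_scipy():
    meta = make_meta(n_batches=1, timepoints=(0.0, 2.0, 4.0, 6.0, 8.0),
                     n_replicates=2)
    genes = log_transform(make_matrix(meta, n_features=4, seed=1,
                                      modality="gene"))
    mets = log_transform(make_matrix(meta, n_features=3, seed=2))
    table = spearman_pairs(genes, mets, meta, "B1").table
    from senmetflux.differential import collapse_replicates_median
    g_c, _ = collapse_replicates_median(genes, meta)
    m_c, _ = collapse_replicates_median(mets, meta)
    for _, row in table.iterrows():
        expected = stats.spearmanr(g_c.values.loc[row["gene_id"]],
                                   m_c.values.loc[row["metabolite_id"]]).statistic
        assert row["spearman_rho"] == pytest.approx(float(expected), abs=1e-12)
    assert (table["n_points"] == 5).all()


def test_spearman_pairs_needs_four_timepoints():
    meta = make_meta(n_batches=1, timepoints=(0.0, 2.0, 4.0), n_replicates=2)
    genes = log_transform(make_matrix(meta, n_features=2, modality="gene"))
    mets = log_transform(make_matrix(meta, n_features=2))
    with pytest.raises(ValueError, match="fewer than 4"):
        spearman_pairs(genes, mets, meta, "B1")


def _table(dataset, rows):
    return CorrelationTable(dataset_id=dataset, table=pd.DataFrame(
        rows, columns=["gene_id", "metabolite_id", "spearman_rho", "n_points"]))


def test_overlap_select_requires_all_datasets():
    t1 = _table("D1", [("g1", "m1", 0.9, 6), ("g2", "m1", 0.9, 6)])
    t2 = _table("D2", [("g1", "m1", -0.8, 6), ("g2", "m1", 0.3, 6)])
    out = overlap_select([t1, t2], threshold=0.5)
    # g1-m1 passes (sign consistency not required); g2-m1 fails in D2
    assert len(out) == 1
    assert out.iloc[0]["gene_id"] == "g1"
    assert out.iloc[0]["rho_D2"] == pytest.approx(-0.8)


def test_overlap_select_threshold_is_strict():
    t1 = _table("D1", [("g1", "m1", 0.5, 6)])
    assert overlap_select([t1], threshold=0.5).empty


def test_build_network_and_rank_hubs():
    pairs = pd.DataFrame({"gene_id": ["g1", "g2", "g3"],
                          "metabolite_id": ["m1", "m1", "m2"]})
    g = build_network(pairs)
    assert g.nodes["m1"]["kind"] == "metabolite"
    ranked = rank_hubs(g, top_k=10)
    assert ranked.iloc[0]["node"] == "m1"  # the only connector
    met_only = rank_hubs(g, top_k=10, kind="metabolite")
    assert set(met_only["node"]) <= {"m1", "m2"}


def test_rank_hubs_deterministic_tie_break():
    g = nx.Graph()
    g.add_nodes_from("abcd", kind="gene")
    g.add_edges_from([("a", "b"), ("c", "d")])
    ranked = rank_hubs(g, top_k=4)
    assert list(ranked["node"]) == sorted(ranked["node"])  # all-tied: id order


def test_correlated_gene_sets_sign_and_count():
    tables = [_table(f"D{i}", [("g1", "m1", 0.9, 6), ("g2", "m1", -0.9, 6)])
              for i in range(3)]
    assert correlated_gene_sets(tables, "m1", "positive") == ["g1"]
    assert correlated_gene_sets(tables, "m1", "negative") == ["g2"]
    with pytest.raises(ValueError, match="unknown metabolite"):
        correlated_gene_sets(tables, "m99", "positive")


def test_write_network_outputs(tmp_path):
    pairs = pd.DataFrame({"gene_id": ["g1", "g2", "g3"],
                          "metabolite_id": ["m1", "m1", "m2"]})
    g = build_network(pairs)
    write_network(g, pairs, tmp_path)
    assert (tmp_path / "pairs.tsv").exists()
    sif = (tmp_path / "edges.sif").read_text().splitlines()
    assert len(sif) == 3 and all(" pp " in line for line in sif)
    nodes = pd.read_csv(tmp_path / "nodes.tsv", sep="\t")
    assert len(nodes) == g.number_of_nodes()
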