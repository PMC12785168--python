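"""Hub-influence scoring, target-conservation analysis, subnetwork
extraction and GO over-representation.

The integrated value of influence (IVI) combines degree centrality,
neighborhood connectivity, betweenness, ClusterRank and collective
influence. Each component is min-max normalised; hubness = DC' + NC' and
spreading = BC' + CR' + CI'; IVI = 1 + 99 * minmax(hubness * spreading),
so scores live on [1, 100] with 100 for the most influential node.
Path-based quantities (betweenness, collective-influence balls, clustering
coefficients) use the undirected projection; ClusterRank fan-out uses
out-degrees, reflecting regulatory reach.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .benchmark import benjamini_hochberg
from .inference import GRN
from .overlay import EvidenceNetwork


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def _as_digraph(net: GRN | EvidenceNetwork | nx.DiGraph) -> nx.DiGraph:
    if isinstance(net, nx.DiGraph):
        return net
    g = nx.DiGraph()
    for r, t in zip(net.edges["regulator"], net.edges["target"]):
        g.add_edge(r, t)
    return g


def ivi(net: GRN | EvidenceNetwork | nx.DiGraph, l: int = 2) -> pd.DataFrame:
    """Per-node component centralities and the combined IVI score."""
    g = _as_digraph(net)
    if g.number_of_nodes() < 3:
        raise ValueError("IVI needs at least 3 nodes")
    nodes = sorted(g.nodes)
    und = g.to_undirected()

    deg_out = dict(g.out_degree())
    deg_in = dict(g.in_degree())
    k_und = dict(und.degree())

    dc = np.array([deg_out[v] + deg_in[v] for v in nodes], dtype=float)
    nc = np.array(
        [
            np.mean([k_und[u] for u in und.neighbors(v)]) if k_und[v] else 0.0
            for v in nodes
        ]
    )
    bc_map = nx.betweenness_centrality(und, normalized=True)
    bc = np.array([bc_map[v] for v in nodes])
    cc = nx.clustering(und)
    cr = np.array(
        [
            10 ** (-cc[v]) * sum(deg_out[u] + 1 for u in g.successors(v))
            for v in nodes
        ]
    )
    ci = np.empty(len(nodes))
    for i, v in enumerate(nodes):
        sphere = nx.descendants_at_distance(und, v, l)
        ci[i] = (k_und[v] - 1) * sum(k_und[u] - 1 for u in sphere)

    dc_n, nc_n, bc_n = _minmax(dc), _minmax(nc), _minmax(bc)
    cr_n, ci_n = _minmax(cr), _minmax(ci)
    hubness = dc_n + nc_n
    spreading = bc_n + cr_n + ci_n
    score = 1 + 99 * _minmax(hubness * spreading)

    return pd.DataFrame(
        {
            "node": nodes,
            "out_degree": [deg_out[v] for v in nodes],
            "in_degree": [deg_in[v] for v in nodes],
            "degree": dc,
            "neighborhood_connectivity": nc,
            "betweenness": bc,
            "clusterrank": cr,
            "collective_influence": ci,
            "hubness": hubness,
            "spreading": spreading,
            "ivi": score,
        }
    ).set_index("node")


@dataclass
class ConservationTable:
    table: pd.DataFrame  # per TF: mean_connectivity, conservation, n_organs
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def target_conservation(networks: dict[str, GRN]) -> ConservationTable:
    """Per-TF mean out-degree across organ networks and the percentage of
    targets conserved in every organ network containing the TF (denominator:
    the union of its targets), with an OLS fit of conservation on mean
    connectivity."""
    targets_by_tf: dict[str, list[set[str]]] = {}
    for grn in networks.values():
        per_tf: dict[str, set[str]] = {}
        for r, t in zip(grn.edges["regulator"], grn.edges["target"]):
            per_tf.setdefault(r, set()).add(t)
        for tf, t in per_tf.items():
            targets_by_tf.setdefault(tf, []).append(t)

    rows = []
    for tf in sorted(targets_by_tf):
        sets = targets_by_tf[tf]
        mean_conn = float(np.mean([len(s) for s in sets]))
        if len(sets) >= 2:
            conserved = set.intersection(*sets)
            union = set.union(*sets)
            conservation = 100.0 * len(conserved) / len(union)
        else:
            conservation = np.nan
        rows.append((tf, mean_conn, conservation, len(sets)))
    table = pd.DataFrame(
        rows, columns=["tf", "mean_connectivity", "conservation", "n_organs"]
    ).set_index("tf")

    fit_rows = table.dropna(subset=["conservation"])
    if len(fit_rows) >= 3 and fit_rows["mean_connectivity"].nunique() > 1:
        res = stats.linregress(
            fit_rows["mean_connectivity"], fit_rows["conservation"]
        )
        slope, intercept = float(res.slope), float(res.intercept)
        r2, p = float(res.rvalue**2), float(res.pvalue)
    else:
        slope = intercept = r2 = p = np.nan
    return ConservationTable(table, slope, intercept, r2, p)


def extract_subnetwork(
    net: GRN | EvidenceNetwork, genes: list[str] | set[str], mode: str = "induced"
):
    """targets_of: edges out of the listed TFs; regulators_of: edges into the
    listed genes; induced: both endpoints listed. Attributes preserved."""
    genes = set(genes)
    edges = net.edges
    if mode == "targets_of":
        mask = edges["regulator"].isin(genes)
    elif mode == "regulators_of":
        mask = edges["target"].isin(genes)
    elif mode == "induced":
        mask = edges["regulator"].isin(genes) & edges["target"].isin(genes)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    sub = edges[mask].reset_index(drop=True)
    if isinstance(net, EvidenceNetwork):
        return EvidenceNetwork(sub, dict(net.provenance))
    return GRN(sub, net.threshold_percent, dict(net.provenance))


def ora(
    target_set: set[str],
    annotation: dict[str, set[str]],
    universe: set[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms in a gene set,
    BH-adjusted across all tested terms (those with >= 1 hit in the set)."""
    if not universe:
        raise ValueError("empty universe")
    if not target_set:
        raise ValueError("empty target set")
    if not target_set <= universe:
        raise ValueError("target set not contained in universe")

    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotation.items():
        if gene not in universe:
            continue
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)

    m_universe = len(universe)
    n_set = len(target_set)
    rows = []
    for term in sorted(term_genes):
        members = term_genes[term]
        k = len(members & target_set)
        if k == 0:
            continue
        # P(X >= k), X ~ Hypergeom(M=universe, n=term size, N=set size)
        p = float(stats.hypergeom.sf(k - 1, m_universe, len(members), n_set))
        rows.append((term, k, len(members), p))
    table = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p_value"])
    if table.empty:
        return table.assign(p_adjusted=[], significant=[])
    table["p_adjusted"] = benjamini_hochberg(table["p_value"].to_numpy())
    table["significant"] = table["p_adjusted"] < fdr
    return table.sort_values("p_value").reset_index(drop=True)
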