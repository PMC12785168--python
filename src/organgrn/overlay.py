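"""Evidence overlay: annotate inferred edges with auxiliary support layers.

The network topology is fixed by the tree-ensemble inference; co-expression,
promoter-motif and open-chromatin-motif pairs are mapped onto the existing
edges as boolean flags, never adding or removing interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .inference import GRN

EVIDENCE_LAYERS = ("coexp", "promoter_motif", "ocs_motif")


@dataclass
class EvidenceNetwork:
    """GRN edges with evidence flags and evidence_count in {1..4}."""

    edges: pd.DataFrame  # regulator, target, weight, rank, flags, evidence_count
    provenance: dict = field(default_factory=dict)

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["regulator"], self.edges["target"]))


def overlay(
    grn: GRN,
    coexp_pairs: set[tuple[str, str]],
    promoter_pairs: set[tuple[str, str]],
    ocs_pairs: set[tuple[str, str]],
) -> EvidenceNetwork:
    """Flag each edge by membership in the three directed evidence-pair
    sets; auxiliary pairs absent from the network are ignored."""
    edges = grn.edges.copy().reset_index(drop=True)
    keys = list(zip(edges["regulator"], edges["target"]))
    edges["genie3"] = True
    for name, pairs in zip(EVIDENCE_LAYERS, (coexp_pairs, promoter_pairs, ocs_pairs)):
        edges[name] = [k in pairs for k in keys]
    edges["evidence_count"] = 1 + edges[list(EVIDENCE_LAYERS)].sum(axis=1)
    return EvidenceNetwork(edges, dict(grn.provenance))


def evidence_histogram(net: EvidenceNetwork) -> dict:
    """Proportions of edges per evidence count, and per-layer support rates."""
    n = len(net.edges)
    if n == 0:
        raise ValueError("empty evidence network")
    by_count = (
        net.edges["evidence_count"].value_counts(normalize=True).sort_index()
    )
    return {
        "by_count": {int(k): float(v) for k, v in by_count.items()},
        "by_layer": {
            layer: float(net.edges[layer].mean()) for layer in EVIDENCE_LAYERS
        },
        "any_additional": float((net.edges["evidence_count"] > 1).mean()),
        "n_edges": n,
    }


def organ_overlap(networks: dict[str, GRN]) -> pd.DataFrame:
    """Label every edge of the union with the number of organ networks
    containing it; returns regulator, target, organ_count."""
    if not networks:
        raise ValueError("no networks supplied")
    counts: dict[tuple[str, str], int] = {}
    for grn in networks.values():
        for edge in grn.edge_set:
            counts[edge] = counts.get(edge, 0) + 1
    rows = [(r, t, c) for (r, t), c in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["regulator", "target", "organ_count"])


def organ_overlap_distribution(networks: dict[str, GRN]) -> pd.Series:
    table = organ_overlap(networks)
    return table["organ_count"].value_counts(normalize=True).sort_index()
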