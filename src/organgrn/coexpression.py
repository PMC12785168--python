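"""Per-study co-expression ranking and cross-study aggregation.

Each study contributes a highest-reciprocal-rank (HRR) matrix: genes are
ranked per row by Pearson correlation, HRR(A,B) = max(rank(A,B), rank(B,A)),
and only pairs within the top 1% best ranks of either gene are retained.
Studies are then aggregated by counting, per pair, the number of studies in
which the pair was retained; a per-gene top-1%-frequency filter removes
low-recurrence noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("organgrn")


@dataclass
class HrrMatrix:
    """Retained symmetric pairs with their HRR value (smaller = stronger)."""

    genes: list[str]
    pairs: pd.DataFrame  # columns: gene_a, gene_b (a < b), hrr

    def hrr_of(self, a: str, b: str) -> int | None:
        a, b = sorted((a, b))
        match = self.pairs[(self.pairs["gene_a"] == a) & (self.pairs["gene_b"] == b)]
        return int(match["hrr"].iloc[0]) if len(match) else None


@dataclass
class AggregatedGCN:
    """Undirected pairs with cross-study frequency, after the noise filter."""

    pairs: pd.DataFrame  # columns: gene_a, gene_b, frequency
    n_studies: int = 0
    prefilter_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)


def study_filter(fpkm: pd.DataFrame, min_fpkm: float = 0.5) -> pd.DataFrame:
    """Drop genes below ``min_fpkm`` in every sample of the study."""
    if fpkm.shape[1] == 0:
        raise ValueError("study has no samples")
    keep = (fpkm >= min_fpkm).any(axis=1)
    return fpkm.loc[keep]


def pcc_rank(fpkm_study: pd.DataFrame) -> pd.DataFrame:
    """Per-gene descending-PCC partner ranks (1 = best partner).

    Constant genes have undefined correlations and are dropped with a
    warning. Ties are broken by partner identifier so ranks are a
    deterministic permutation 1..n-1 of each row.
    """
    sd = fpkm_study.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "dropping %d constant genes from correlation ranking", int(constant.sum())
        )
        fpkm_study = fpkm_study.loc[~constant]
    genes = list(fpkm_study.index)
    n = len(genes)
    if n < 2:
        raise ValueError("need at least 2 non-constant genes")
    pcc = np.corrcoef(fpkm_study.to_numpy(dtype=float))
    np.fill_diagonal(pcc, -np.inf)  # self excluded
    ranks = np.empty((n, n), dtype=int)
    for i in range(n):
        # PCC descending, ties broken by partner id; self sorts last (-inf)
        order = sorted(range(n), key=lambda j: (-pcc[i, j], genes[j]))
        for r, j in enumerate(order[: n - 1], start=1):
            ranks[i, j] = r
        ranks[i, i] = 0
    return pd.DataFrame(ranks, index=genes, columns=genes)


def top_rank_cutoff(n_genes: int, top_fraction: float = 0.01) -> int:
    """Per-gene best-rank cutoff: ceil(top_fraction * (n-1)), at least 1."""
    return max(1, math.ceil(top_fraction * (n_genes - 1)))


def hrr(ranks: pd.DataFrame, top_fraction: float = 0.01) -> HrrMatrix:
    """HRR(A,B) = max of the two directed ranks, retaining a pair only when
    either directed rank passes the per-gene top-1% cutoff."""
    genes = list(ranks.index)
    n = len(genes)
    cutoff = top_rank_cutoff(n, top_fraction)
    r = ranks.to_numpy()
    records = []
    for i in range(n):
        for j in range(i + 1, n):
            if r[i, j] <= cutoff or r[j, i] <= cutoff:
                a, b = sorted((genes[i], genes[j]))
                records.append((a, b, int(max(r[i, j], r[j, i]))))
    pairs = pd.DataFrame(records, columns=["gene_a", "gene_b", "hrr"])
    pairs = pairs.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    return HrrMatrix(genes, pairs)


def aggregate(hrr_list: list[HrrMatrix], top_fraction: float = 0.01) -> AggregatedGCN:
    """Count, per pair, the studies in which it was retained, then keep a
    pair iff its frequency is within the top 1% frequencies of either
    endpoint gene (>= at the quantile boundary)."""
    if not hrr_list:
        raise ValueError("aggregate: empty HRR list")
    counts: dict[tuple[str, str], int] = {}
    for m in hrr_list:
        for a, b in zip(m.pairs["gene_a"], m.pairs["gene_b"]):
            counts[(a, b)] = counts.get((a, b), 0) + 1
    prefilter = pd.DataFrame(
        [(a, b, f) for (a, b), f in sorted(counts.items())],
        columns=["gene_a", "gene_b", "frequency"],
    )

    # per-gene frequency threshold: the frequency of the ceil(1% * deg)-th
    # best pair of that gene; a pair survives if it passes from either side
    by_gene: dict[str, list[int]] = {}
    for a, b, f in prefilter.itertuples(index=False):
        by_gene.setdefault(a, []).append(f)
        by_gene.setdefault(b, []).append(f)
    thresholds = {}
    for gene, freqs in by_gene.items():
        freqs = sorted(freqs, reverse=True)
        k = max(1, math.ceil(top_fraction * len(freqs)))
        thresholds[gene] = freqs[k - 1]
    keep = [
        f >= thresholds[a] or f >= thresholds[b]
        for a, b, f in prefilter.itertuples(index=False)
    ]
    pairs = prefilter[keep].reset_index(drop=True)
    return AggregatedGCN(pairs, n_studies=len(hrr_list), prefilter_pairs=prefilter)


def tf_target_pairs(gcn: AggregatedGCN, tfs: set[str]) -> set[tuple[str, str]]:
    """Expand undirected pairs into directed TF->partner evidence pairs;
    TF-TF pairs contribute both directions."""
    out: set[tuple[str, str]] = set()
    for a, b in zip(gcn.pairs["gene_a"], gcn.pairs["gene_b"]):
        if a in tfs:
            out.add((a, b))
        if b in tfs:
            out.add((b, a))
    return out
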