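"""Gold-standard benchmarking: Fisher enrichment, AUROC/AUPR, permutation nulls.

Inferred networks are compared against experimentally derived TF->target
sets. Edges are filtered to regulators shared by the prediction and the
gold standard, labelled by gold membership, and the ranked weights are
swept to produce AUROC (rank statistic, ties contribute 1/2) and AUPR
(precision-recall step integration). Significance comes from a null of
weight shuffles over the fixed edge set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats

from .inference import RankedEdgeList

logger = logging.getLogger("organgrn")


@dataclass
class GoldStandard:
    """TF -> experimentally supported target set."""

    targets: dict[str, set[str]]
    min_targets: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [tf for tf, t in self.targets.items() if not t]
        if empty:
            raise ValueError(f"gold standard TFs with empty target sets: {empty}")

    @property
    def pair_set(self) -> set[tuple[str, str]]:
        return {(tf, g) for tf, targets in self.targets.items() for g in targets}

    @property
    def tfs(self) -> set[str]:
        return set(self.targets)


def build_gold_standard(
    assignments: dict[str, dict[str, set[str]]], min_targets: int = 1000
) -> GoldStandard:
    """Union target sets per TF across experiments, keeping only TFs with
    strictly more than ``min_targets`` assigned targets."""
    if not assignments:
        raise ValueError("no assignments supplied")
    merged: dict[str, set[str]] = {}
    for exp, per_tf in assignments.items():
        for tf, targets in per_tf.items():
            merged.setdefault(tf, set()).update(targets)
    kept = {tf: t for tf, t in merged.items() if len(t) > min_targets}
    return GoldStandard(kept, min_targets, {"experiments": sorted(assignments)})


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def fisher_enrichment(
    pred: set, gold: set, universe: set, name: str = "comparison"
) -> dict:
    """One 2x2 enrichment entry: two-sided exact p, odds ratio with
    Haldane-Anscombe correction when a cell is zero."""
    if not universe:
        raise ValueError("empty universe")
    if not pred <= universe:
        raise ValueError("pred set not contained in universe")
    if not gold <= universe:
        raise ValueError("gold set not contained in universe")
    a = len(pred & gold)
    b = len(pred - gold)
    c = len(gold - pred)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return {
        "name": name,
        "a": a, "b": b, "c": c, "d": d,
        "odds_ratio": float(odds),
        "log2_odds_ratio": float(np.log2(odds)),
        "p_value": float(p),
        "overlap": a,
    }


def fisher_batch(entries: list[dict]) -> pd.DataFrame:
    """BH-adjust a batch of fisher_enrichment entries in one call."""
    table = pd.DataFrame(entries)
    table["p_adjusted"] = benjamini_hochberg(table["p_value"].to_numpy())
    return table


# ---------------------------------------------------------------------------
# AUROC / AUPR
# ---------------------------------------------------------------------------

def _labelled_weights(
    ranked: RankedEdgeList, gold: GoldStandard
) -> tuple[np.ndarray, np.ndarray]:
    edges = ranked.edges
    shared = edges["regulator"].isin(gold.tfs)
    edges = edges[shared]
    if edges.empty:
        raise ValueError("no edges from gold-standard regulators")
    gold_pairs = gold.pair_set
    labels = np.fromiter(
        ((r, t) in gold_pairs for r, t in zip(edges["regulator"], edges["target"])),
        dtype=bool, count=len(edges),
    )
    return edges["weight"].to_numpy(dtype=float), labels


def auroc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-statistic AUROC; tied scores contribute 1/2 per discordant pair."""
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    ranks = stats.rankdata(scores)  # midranks handle ties
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def aupr_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """Step integration of the precision-recall sweep (descending scores,
    tied scores processed as one block)."""
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("need at least one positive and one negative label")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order].astype(float)
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # block boundaries: last index of each run of equal scores
    last_of_block = np.flatnonzero(np.r_[s[1:] != s[:-1], True])
    precision = tp[last_of_block] / (tp[last_of_block] + fp[last_of_block])
    recall = tp[last_of_block] / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def roc_pr(ranked: RankedEdgeList, gold: GoldStandard) -> tuple[float, float]:
    """AUROC and AUPR of a ranked edge list against a gold standard, after
    restricting to regulators present in both networks."""
    weights, labels = _labelled_weights(ranked, gold)
    if labels.all() or not labels.any():
        raise ValueError(
            "degenerate labels: no positives" if not labels.any()
            else "degenerate labels: no negatives"
        )
    return auroc_from_scores(weights, labels), aupr_from_scores(weights, labels)


def permutation_test(
    ranked: RankedEdgeList,
    gold: GoldStandard,
    n_perm: int = 1000,
    percentiles: tuple[float, float] = (2.5, 97.5),
    seed: int = 0,
) -> dict:
    """Weight-shuffle null over the fixed edge set; the observed metric is
    significant when above the upper percentile of its null."""
    if n_perm < 20:
        logger.warning("n_perm=%d: percentile estimates will be unstable", n_perm)
    weights, labels = _labelled_weights(ranked, gold)
    obs_auroc = auroc_from_scores(weights, labels)
    obs_aupr = aupr_from_scores(weights, labels)
    rng = np.random.default_rng(seed)
    null_auroc = np.empty(n_perm)
    null_aupr = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = rng.permutation(weights)
        null_auroc[i] = auroc_from_scores(shuffled, labels)
        null_aupr[i] = aupr_from_scores(shuffled, labels)
    lo, hi = percentiles
    out = {
        "auroc": obs_auroc,
        "aupr": obs_aupr,
        "n_perm": n_perm,
        "seed": seed,
        "percentiles": percentiles,
    }
    for name, null in (("auroc", null_auroc), ("aupr", null_aupr)):
        out[f"null_{name}_mean"] = float(null.mean())
        out[f"null_{name}_lo"] = float(np.percentile(null, lo))
        out[f"null_{name}_hi"] = float(np.percentile(null, hi))
        out[f"{name}_significant"] = bool(out[name] > out[f"null_{name}_hi"])
    return out


def overlap_percentage(k: int, n: int, digits: int = 0) -> float:
    """100*k/n rounded half-away-from-zero to ``digits`` decimal places."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    quant = Decimal(1).scaleb(-digits)
    value = Decimal(100 * k) / Decimal(n)
    return float(value.quantize(quant, rounding=ROUND_HALF_UP))
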