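"""Tree-ensemble inference of a ranked, directed TF->target edge list.

For each target gene the unit-variance-scaled expression profile is
regressed on all transcription-factor profiles (the target's own profile
excluded) with a random forest; the edge weight for a TF is the mean over
trees of the total variance reduction its splits achieve. Because each
response is scaled to unit variance, the weights of one target sum to
roughly the fraction of its variance the forest explains, making weights
comparable across targets, and all edges can be pooled into a single
descending ranking.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

logger = logging.getLogger("organgrn")

EDGE_COLUMNS = ["regulator", "target", "weight"]


@dataclass
class RankedEdgeList:
    """All TF->target edges sorted by weight descending (deterministic ties)."""

    edges: pd.DataFrame  # columns: regulator, target, weight
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class GRN:
    """Top-k% thresholded network."""

    edges: pd.DataFrame  # columns: regulator, target, weight, rank
    threshold_percent: float = 100.0
    provenance: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["regulator"], self.edges["target"]))

    @property
    def summary(self) -> dict:
        return {
            "n_tfs": int(self.edges["regulator"].nunique()),
            "n_genes": int(
                pd.concat([self.edges["regulator"], self.edges["target"]]).nunique()
            ),
            "n_edges": self.n_edges,
        }


def _target_seed(global_seed: int, gene_id: str) -> int:
    # stable per-target stream: results independent of target scheduling
    return (int(global_seed) + zlib.crc32(gene_id.encode())) % (2**31)


def sort_edges(edges: pd.DataFrame) -> pd.DataFrame:
    """Global deterministic ordering: weight desc, then regulator, target."""
    return edges.sort_values(
        ["weight", "regulator", "target"], ascending=[False, True, True]
    ).reset_index(drop=True)


def infer_grn(
    expr: pd.DataFrame,
    tfs: set[str] | list[str],
    n_trees: int = 2000,
    k_rule: str = "sqrt",
    seed: int = 123,
    targets: list[str] | None = None,
) -> RankedEdgeList:
    """GENIE3-style inference.

    Parameters
    ----------
    expr : genes x samples matrix (counts or any abundance unit).
    tfs : candidate regulators; must intersect the matrix's genes.
    n_trees : trees per target ensemble (2000 keeps edge weights stable).
    k_rule : 'sqrt' (random sqrt(p) candidates per split) or 'all'.
    seed : global seed; each target derives its own stream from it.
    """
    tf_list = sorted(set(tfs) & set(expr.index))
    if len(tf_list) < 2:
        raise ValueError("need at least 2 TFs present in the expression matrix")
    if expr.shape[1] < 10:
        raise ValueError("need at least 10 samples")
    if k_rule not in {"sqrt", "all"}:
        raise ValueError(f"unknown k_rule {k_rule!r}")
    max_features = "sqrt" if k_rule == "sqrt" else 1.0

    target_list = sorted(targets) if targets is not None else list(expr.index)
    tf_mat = expr.loc[tf_list].to_numpy(dtype=float).T  # samples x TFs
    tf_index = {tf: j for j, tf in enumerate(tf_list)}

    records: list[tuple[str, str, float]] = []
    for gene in target_list:
        y = expr.loc[gene].to_numpy(dtype=float)
        sd = y.std()
        if sd == 0:
            logger.warning("gene %s has constant expression; skipped", gene)
            continue
        y = (y - y.mean()) / sd
        if gene in tf_index:
            keep = [j for tf, j in tf_index.items() if tf != gene]
            predictors = [tf_list[j] for j in keep]
            X = tf_mat[:, keep]
        else:
            predictors = tf_list
            X = tf_mat
        forest = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=max_features,
            bootstrap=True,
            random_state=_target_seed(seed, gene),
            n_jobs=1,
        )
        forest.fit(X, y)
        # mean over trees of unnormalized impurity reduction per predictor:
        # with a unit-variance response these sum to ~ the explained variance
        importances = np.mean(
            [t.tree_.compute_feature_importances(normalize=False)
             for t in forest.estimators_],
            axis=0,
        )
        records.extend(
            (tf, gene, float(w)) for tf, w in zip(predictors, importances)
        )

    edges = sort_edges(pd.DataFrame(records, columns=EDGE_COLUMNS))
    provenance = {
        "n_trees": n_trees,
        "k_rule": k_rule,
        "seed": seed,
        "n_tfs": len(tf_list),
        "n_targets": len(target_list),
        "n_samples": int(expr.shape[1]),
    }
    return RankedEdgeList(edges, provenance)


def threshold_top_percent(ranked: RankedEdgeList, percent: float) -> GRN:
    """Keep the first ceil(percent/100 * N) edges of the deterministic order."""
    if not 0 < percent <= 100:
        raise ValueError("percent must be in (0, 100]")
    if len(ranked) == 0:
        raise ValueError("cannot threshold an empty edge list")
    n_keep = math.ceil(percent / 100 * len(ranked))
    edges = ranked.edges.iloc[:n_keep].copy().reset_index(drop=True)
    edges["rank"] = np.arange(1, len(edges) + 1)
    return GRN(edges, percent, dict(ranked.provenance))


def read_edges_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})


def write_edges_tsv(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)
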