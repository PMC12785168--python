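"""Ground-truth regulatory systems and every downstream input the pipeline
consumes, generated with the statistical structure the analysis assumes.

A truth network of TF->target edges with signed effects drives log-normal
TF expression through a softplus response into target expression, per
organ (each edge is active either in all organs or in exactly one),
with study-block scale factors and negative-binomial counts. Promoters are
i.i.d. background with the regulator's strongest motif word planted under
true edges at a configurable rate; open-chromatin intervals cover a subset
of planted sites; gold standards are noisy subsamples of the truth.
Everything is bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomicInterval, PromoterSet

DEFAULT_ORGANS = ("root", "leaf", "flower", "fruit", "seed")

#: lower bound on |effect| so every truth edge is a real dependency
MIN_EFFECT = 0.5


@dataclass
class SimulationConfig:
    n_tf: int = 20
    n_gene: int = 100            # total genes, TFs included
    organs: tuple[str, ...] = DEFAULT_ORGANS
    n_samples_per_organ: int = 200
    n_studies: int = 4
    mean_outdegree: float = 8.0
    effect_sd: float = 2.0
    noise_sd: float = 0.1
    organ_share: float = 0.25    # fraction of edges active in every organ
    basal_activity: float = 3.0  # basal transcriptional drive of targets
    study_scale_sd: float = 0.2  # log-sd of per-study per-gene scale factors
    motif_plant_rate: float = 0.8
    ocs_cover_rate: float = 0.6
    gold_sensitivity: float = 0.9
    gold_fp_rate: float = 0.1
    gold_min_targets: int = 5
    nb_dispersion: float = 0.1
    promoter_len: int = 2000
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 123

    def __post_init__(self) -> None:
        for name in ("organ_share", "motif_plant_rate", "ocs_cover_rate",
                     "gold_sensitivity", "gold_fp_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_tf", "n_gene", "n_samples_per_organ", "n_studies"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_gene <= self.n_tf:
            raise ValueError("n_gene must exceed n_tf")


@dataclass
class SyntheticTruth:
    tf_ids: list[str]
    gene_ids: list[str]
    edges: list[tuple[str, str, float]]  # (regulator, target, effect)
    organ_masks: dict[str, set[tuple[str, str]]]
    pwm_by_tf: dict[str, np.ndarray]  # TF -> 4 x W count matrix
    seed: int

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {(r, t) for r, t, _ in self.edges}

    def edges_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["regulator", "target", "effect"])


@dataclass
class PlantedPromoters(PromoterSet):
    """Promoter set that remembers which (tf, gene, offset) sites were planted."""

    planted: list[tuple[str, str, int]] = field(default_factory=list)


def _derive_seed(seed: int, label: str) -> int:
    return (int(seed) + zlib.crc32(label.encode())) % (2**31)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _random_pfm(rng: np.random.Generator) -> np.ndarray:
    """One dominant base per column (~1.5 bits/column), width 8-12: wide
    enough that a perfect site clears p <= 1e-4 under uniform background."""
    width = int(rng.integers(8, 13))
    counts = np.full((4, width), 5.0)
    dominant = rng.integers(0, 4, size=width)
    counts[dominant, np.arange(width)] = 85.0
    return counts


def generate_truth(cfg: SimulationConfig) -> SyntheticTruth:
    """Heavy-tailed out-degrees (log-normal, mean ~ mean_outdegree), targets
    uniform over the other genes, signed normal effects; ``organ_share`` of
    edges active everywhere, the rest in exactly one organ."""
    if cfg.mean_outdegree >= cfg.n_gene - cfg.n_tf:
        raise ValueError("mean_outdegree must be below the non-TF gene count")
    rng = np.random.default_rng(_derive_seed(cfg.seed, "truth"))
    tf_ids = [f"TF{i:03d}" for i in range(cfg.n_tf)]
    gene_ids = tf_ids + [f"G{i:03d}" for i in range(cfg.n_gene - cfg.n_tf)]

    sigma = 0.5
    mu = np.log(cfg.mean_outdegree) - sigma**2 / 2
    edges: list[tuple[str, str, float]] = []
    # TF profiles are exogenous drivers; edges point to non-TF genes so the
    # response model stays acyclic and every edge is expressed in the data
    candidates = gene_ids[cfg.n_tf:]
    for tf in tf_ids:
        k = int(np.clip(round(rng.lognormal(mu, sigma)), 1, len(candidates)))
        targets = rng.choice(len(candidates), size=k, replace=False)
        for idx in targets:
            # magnitude bounded away from zero: an edge whose effect is ~0
            # would be a truth label without an actual dependency
            magnitude = MIN_EFFECT + abs(float(rng.normal(0.0, cfg.effect_sd)))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            edges.append((tf, candidates[idx], sign * magnitude))

    n_edges = len(edges)
    order = rng.permutation(n_edges)
    n_shared = int(round(cfg.organ_share * n_edges))
    shared = {(edges[i][0], edges[i][1]) for i in order[:n_shared]}
    masks: dict[str, set[tuple[str, str]]] = {o: set(shared) for o in cfg.organs}
    for i in order[n_shared:]:
        organ = cfg.organs[int(rng.integers(0, len(cfg.organs)))]
        masks[organ].add((edges[i][0], edges[i][1]))

    pwms = {}
    for tf in tf_ids:
        pwm_rng = np.random.default_rng(_derive_seed(cfg.seed, f"pfm:{tf}"))
        pwms[tf] = _random_pfm(pwm_rng)
    return SyntheticTruth(tf_ids, gene_ids, edges, masks, pwms, cfg.seed)


def gene_lengths(truth: SyntheticTruth) -> pd.Series:
    """Per-gene lengths (bases), identical across organs."""
    rng = np.random.default_rng(_derive_seed(truth.seed, "lengths"))
    return pd.Series(
        rng.integers(500, 3001, size=len(truth.gene_ids)),
        index=truth.gene_ids, name="length",
    )


def simulate_expression(
    truth: SyntheticTruth, organ: str, cfg: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series, pd.DataFrame]:
    """Abundance matrix, matching negative-binomial counts, gene lengths and
    sample metadata for one organ.

    TF profiles are log-normal; each regulated target is
    softplus(sum of active effects x regulator abundance) + Gaussian noise;
    unregulated genes carry independent log-normal baseline variation.
    Samples are split into ``n_studies`` blocks, each with per-gene
    log-normal scale factors.
    """
    if organ not in truth.organ_masks:
        raise ValueError(f"unknown organ {organ!r}")
    rng = np.random.default_rng(_derive_seed(truth.seed, f"expr:{organ}"))
    n = cfg.n_samples_per_organ
    genes = truth.gene_ids
    tf_index = {tf: i for i, tf in enumerate(truth.tf_ids)}

    tf_abund = rng.lognormal(0.0, 1.0, size=(len(truth.tf_ids), n))
    active = truth.organ_masks[organ]
    regulated = {t for _, t, _ in truth.edges}
    parents: dict[str, list[tuple[int, float]]] = {}
    for r, t, e in truth.edges:
        if (r, t) in active:
            parents.setdefault(t, []).append((tf_index[r], e))

    abund = np.empty((len(genes), n))
    for i, g in enumerate(genes):
        if g in tf_index:
            abund[i] = tf_abund[tf_index[g]]
        elif g in parents:
            # basal drive keeps repression inside the responsive region of
            # the softplus: without it a net-negative predictor saturates at
            # zero and repressive edges would leave no trace in the data
            z = np.full(n, cfg.basal_activity)
            for j, e in parents[g]:
                z += e * tf_abund[j]
            abund[i] = _softplus(z) + rng.normal(0.0, cfg.noise_sd, size=n)
        elif g in regulated:
            # regulated gene whose regulators are all inactive in this
            # organ: silent apart from leaky noise, so organ-specific
            # targets drop out of the organ's expressed set
            abund[i] = np.abs(rng.normal(0.0, cfg.noise_sd, size=n))
        else:
            abund[i] = rng.lognormal(0.0, 1.0, size=n)
    np.clip(abund, 0.0, None, out=abund)

    sample_ids = [f"{organ}_s{i:03d}" for i in range(n)]
    study_of = [f"{organ}_study{(i * cfg.n_studies) // n}" for i in range(n)]
    meta = pd.DataFrame({"organ": organ, "study": study_of}, index=sample_ids)

    # per-study per-gene multiplicative scale factors
    for study in sorted(set(study_of)):
        cols = [i for i, s in enumerate(study_of) if s == study]
        srng = np.random.default_rng(_derive_seed(truth.seed, f"study:{study}"))
        factors = srng.lognormal(0.0, cfg.study_scale_sd, size=len(genes))
        abund[:, cols] *= factors[:, None]

    lengths = gene_lengths(truth)
    mean_counts = abund * (lengths.to_numpy()[:, None] / 1000.0) * 30.0
    shape = 1.0 / cfg.nb_dispersion
    lam = rng.gamma(shape, np.maximum(mean_counts, 1e-12) / shape)
    counts = rng.poisson(lam)

    abund_df = pd.DataFrame(abund, index=genes, columns=sample_ids)
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)
    return abund_df, counts_df, lengths, meta


def random_promoters(
    gene_ids: list[str],
    length: int = 2000,
    background: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> PromoterSet:
    """I.i.d. background promoters at the stated base composition."""
    rng = np.random.default_rng(_derive_seed(seed, "promoters"))
    bases = np.array(list("ACGT"))
    seqs = {
        g: "".join(rng.choice(bases, size=length, p=background))
        for g in gene_ids
    }
    return PromoterSet(seqs)


def plant_motifs(
    truth: SyntheticTruth,
    promoters: PromoterSet,
    q: float,
    seed: int = 0,
) -> PlantedPromoters:
    """For each true edge, with probability ``q`` write the regulator's
    maximum-scoring motif word at a uniform random position (and strand) of
    the target promoter."""
    from .annotation import reverse_complement
    from .motifs import BASES

    rng = np.random.default_rng(_derive_seed(seed, "plant"))
    seqs = dict(promoters.sequences)
    planted: list[tuple[str, str, int]] = []
    for r, t, _ in truth.edges:
        if t not in seqs:
            continue
        counts = truth.pwm_by_tf[r]
        word = "".join(BASES[i] for i in counts.argmax(axis=0))
        seq = seqs[t]
        if len(seq) < len(word):
            continue
        if rng.random() >= q:
            continue
        pos = int(rng.integers(0, len(seq) - len(word) + 1))
        if rng.random() < 0.5:
            word = reverse_complement(word)
        seqs[t] = seq[:pos] + word + seq[pos + len(word):]
        planted.append((r, t, pos))
    return PlantedPromoters(seqs, dict(promoters.intervals), planted)


# ---------------------------------------------------------------------------
# Genomic layout: genome, gene models, open-chromatin intervals
# ---------------------------------------------------------------------------

GENE_BODY_LEN = 1000
SPACER_LEN = 100


def synth_genome(
    truth: SyntheticTruth, promoters: PromoterSet, seed: int = 0
) -> tuple[dict[str, str], dict[str, GeneModel], dict[str, GenomicInterval]]:
    """Lay promoters and gene bodies on one contig: for every gene,
    [spacer][promoter][gene body], all on the + strand, so extracting
    promoters from the genome reproduces the input promoter set."""
    rng = np.random.default_rng(_derive_seed(seed, "genome"))
    bases = np.array(list("ACGT"))
    chunks: list[str] = []
    genes: dict[str, GeneModel] = {}
    promoter_intervals: dict[str, GenomicInterval] = {}
    pos = 0
    for g in truth.gene_ids:
        spacer = "".join(rng.choice(bases, size=SPACER_LEN))
        promoter = promoters.sequences.get(g, "")
        body = "".join(rng.choice(bases, size=GENE_BODY_LEN))
        chunks.extend([spacer, promoter, body])
        prom_start = pos + SPACER_LEN
        gene_start = prom_start + len(promoter)
        genes[g] = GeneModel(g, "chr1", gene_start, gene_start + GENE_BODY_LEN, "+")
        if promoter:
            promoter_intervals[g] = GenomicInterval(
                "chr1", prom_start, gene_start, "+", g
            )
        pos = gene_start + GENE_BODY_LEN
    return {"chr1": "".join(chunks)}, genes, promoter_intervals


def make_ocs(
    planted_promoters: PlantedPromoters,
    promoter_intervals: dict[str, GenomicInterval],
    cover_rate: float,
    seed: int = 0,
    flank: int = 75,
) -> list[GenomicInterval]:
    """Open-chromatin intervals covering each planted motif site with
    probability ``cover_rate`` (plus-strand layout coordinates)."""
    rng = np.random.default_rng(_derive_seed(seed, "ocs"))
    out: list[GenomicInterval] = []
    for i, (tf, gene, offset) in enumerate(planted_promoters.planted):
        if gene not in promoter_intervals or rng.random() >= cover_rate:
            continue
        iv = promoter_intervals[gene]
        site = iv.start + offset
        start = max(iv.start, site - flank)
        end = min(iv.end, site + flank + 10)
        out.append(GenomicInterval("chr1", start, end, ".", f"OCS{i:04d}"))
    return out


def corrupt_gold(
    truth: SyntheticTruth,
    organ: str,
    sensitivity: float,
    fp_rate: float,
    seed: int = 0,
    min_targets: int = 0,
):
    """ChIP-like gold standard: keep each active true edge with probability
    ``sensitivity``; add false TF->target pairs at ``fp_rate`` relative to
    the kept count; retain TFs with strictly more than ``min_targets``."""
    from .benchmark import GoldStandard

    if not 0 <= sensitivity <= 1 or not 0 <= fp_rate <= 1:
        raise ValueError("rates must be in [0, 1]")
    if organ not in truth.organ_masks:
        raise ValueError(f"unknown organ {organ!r}")
    rng = np.random.default_rng(_derive_seed(seed, f"gold:{organ}"))
    active = sorted(truth.organ_masks[organ])
    kept = [e for e in active if rng.random() < sensitivity]

    n_fp = int(round(fp_rate * len(kept)))
    true_pairs = truth.edge_set
    false_pairs: set[tuple[str, str]] = set()
    while len(false_pairs) < n_fp:
        tf = truth.tf_ids[int(rng.integers(0, len(truth.tf_ids)))]
        g = truth.gene_ids[int(rng.integers(0, len(truth.gene_ids)))]
        if g != tf and (tf, g) not in true_pairs:
            false_pairs.add((tf, g))

    targets: dict[str, set[str]] = {}
    for tf, g in list(kept) + sorted(false_pairs):
        targets.setdefault(tf, set()).add(g)
    qualified = {tf: t for tf, t in targets.items() if len(t) > min_targets}
    return GoldStandard(qualified, min_targets, {"organ": organ, "seed": seed})
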