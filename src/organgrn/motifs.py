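"""Position-weight-matrix scanning with exact null p-values.

A PFM (base counts/probabilities per column) is converted to a log-odds PWM
against a background composition. The null distribution of the score of a
random W-mer under the background is computed exactly by dynamic programming
over a discretised score lattice, giving the tail probability
P(score >= s); scanning thresholds hits at p <= 1e-4 by default, matching
common motif-scanner defaults. Both strands are scanned and windows
containing N are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import motifs as bio_motifs

from .annotation import GeneModel, GenomicInterval, PromoterSet, \
    assign_intervals_to_genes, extract_interval_sequences

logger = logging.getLogger("organgrn")

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: promoters shorter than this are not scanned (window must fit comfortably)
MIN_SCAN_LENGTH = 50


@dataclass
class PFM:
    """4 x W matrix of base counts (rows A, C, G, T)."""

    motif_id: str
    tf_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("PFM must have 4 rows (A, C, G, T)")
        if self.counts.shape[1] < 4:
            raise ValueError("PFM width must be >= 4")
        if (self.counts < 0).any():
            raise ValueError("PFM counts must be nonnegative")
        if (self.counts.sum(axis=0) == 0).any():
            raise ValueError("PFM has an all-zero column")

    @property
    def width(self) -> int:
        return self.counts.shape[1]


@dataclass
class PWM:
    """Log2-odds matrix with its background and achievable score range."""

    motif_id: str
    tf_id: str
    logodds: np.ndarray
    background: tuple[float, float, float, float]
    pseudocount: float
    _tail_cache: dict = field(default_factory=dict, repr=False)

    @property
    def width(self) -> int:
        return self.logodds.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.logodds.min(axis=0).sum())

    def max_word(self) -> str:
        """The highest-scoring W-mer (ties: first base in A,C,G,T order)."""
        return "".join(BASES[i] for i in self.logodds.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        rc = self.logodds[::-1, ::-1]
        return PWM(self.motif_id, self.tf_id, rc.copy(), self.background,
                   self.pseudocount)


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    sequence_id: str
    start: int  # 0-based forward-strand coordinate
    strand: str
    score: float
    p_value: float


def pfm_to_pwm(
    pfm: PFM,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.01,
) -> PWM:
    """Log2-odds construction: p = (count + pseudocount*bg) / (total + pseudocount)."""
    bg = np.asarray(background, dtype=float)
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must sum to 1")
    totals = pfm.counts.sum(axis=0)
    probs = (pfm.counts + pseudocount * bg[:, None]) / (totals + pseudocount)
    logodds = np.log2(probs / bg[:, None])
    return PWM(pfm.motif_id, pfm.tf_id, logodds, tuple(bg), pseudocount)


# ---------------------------------------------------------------------------
# Exact p-values by dynamic programming
# ---------------------------------------------------------------------------

def scaled_matrix(pwm: PWM, eps: float = 1e-3) -> np.ndarray:
    """The PWM rounded to an integer lattice with bin width ``eps`` bits.

    All p-value machinery and scanning operate on this lattice, so the DP
    tail, the scan threshold and reported hit p-values are mutually exact.
    """
    return np.round(pwm.logodds / eps).astype(np.int64)


def _tail(pwm: PWM, eps: float) -> tuple[np.ndarray, int]:
    """(tail array, min lattice index): tail[k] = P(lattice score >= k + min)."""
    key = round(eps, 12)
    if key not in pwm._tail_cache:
        scaled = scaled_matrix(pwm, eps)
        bg = np.asarray(pwm.background)
        # DP over columns: convolve the running distribution per column
        offset = 0
        current = np.array([1.0])
        for w in range(pwm.width):
            col = scaled[:, w]
            lo, hi = int(col.min()), int(col.max())
            nxt = np.zeros(len(current) + hi - lo)
            for b in range(4):
                shift = int(col[b]) - lo
                nxt[shift:shift + len(current)] += bg[b] * current
            current = nxt
            offset += lo
        tail = np.cumsum(current[::-1])[::-1]
        pwm._tail_cache[key] = (tail, offset)
    return pwm._tail_cache[key]


def _lattice_pvalue(pwm: PWM, lattice_score: int, eps: float) -> float:
    tail, min_idx = _tail(pwm, eps)
    idx = lattice_score - min_idx
    if idx < 0:
        return 1.0
    if idx >= len(tail):
        return float(np.nextafter(0, 1))
    return float(min(1.0, tail[idx]))


def query_index(pwm: PWM, score: float, eps: float = 1e-3) -> int:
    """Conservative lattice index for an arbitrary (float) score query: any
    W-mer whose true score is >= ``score`` has a lattice score of at least
    this index (per-column rounding shifts a word by at most width/2 bins)."""
    return int(np.round(score / eps)) - (pwm.width + 1) // 2


def score_pvalue(pwm: PWM, score: float, eps: float = 1e-3) -> float:
    """P(score of a random background W-mer >= ``score``), exact on the
    eps-lattice (conservative across the lattice guard band); monotone
    nonincreasing in score."""
    if score > pwm.max_score + eps:
        logger.warning("score %.4f exceeds the maximum achievable; p ~ 0", score)
        return float(np.nextafter(0, 1))
    return _lattice_pvalue(pwm, query_index(pwm, score, eps), eps)


def score_threshold(pwm: PWM, p_threshold: float, eps: float = 1e-3) -> int:
    """Smallest lattice score index whose exact tail probability is
    <= p_threshold (may exceed the maximum achievable index: no hits)."""
    tail, min_idx = _tail(pwm, eps)
    idx = int(np.searchsorted(-tail, -p_threshold))  # tail is nonincreasing
    return idx + min_idx


def hit_probability(pwm: PWM, p_threshold: float, eps: float = 1e-3) -> float:
    """Exact per-window probability of a hit at the given p threshold (the
    tail mass at the realised lattice threshold; 0 if unreachable)."""
    tail, min_idx = _tail(pwm, eps)
    idx = score_threshold(pwm, p_threshold, eps) - min_idx
    return float(tail[idx]) if idx < len(tail) else 0.0


# ---------------------------------------------------------------------------
# Scanning
# ---------------------------------------------------------------------------

def encode_sequence(seq: str) -> np.ndarray:
    arr = np.full(len(seq), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        arr[np.frombuffer(seq.upper().encode(), dtype=np.uint8)
            == ord(base)] = idx
    return arr


def _window_lattice_scores(scaled: np.ndarray, encoded: np.ndarray) -> np.ndarray:
    """Integer lattice scores of all windows; windows containing N get the
    sentinel minimum (they can never pass a threshold)."""
    w = scaled.shape[1]
    n_win = len(encoded) - w + 1
    if n_win <= 0:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, w)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n_win, np.iinfo(np.int64).min, dtype=np.int64)
    if valid.any():
        vw = windows[valid].astype(np.intp)
        scores[valid] = scaled[vw, np.arange(w)].sum(axis=1)
    return scores


def scan_sequence(
    pwm: PWM,
    seq: str,
    sequence_id: str = "seq",
    p_threshold: float = 1e-4,
    eps: float = 1e-3,
) -> list[MotifHit]:
    """Scan both strands on the shared score lattice; report hits with
    p <= threshold at forward-strand start coordinates. Sequences shorter
    than the motif yield no hits; windows containing N never hit."""
    if len(seq) < pwm.width:
        return []
    thr = score_threshold(pwm, p_threshold, eps)
    encoded = encode_sequence(seq)
    hits: list[MotifHit] = []
    for strand, matrix in (
        ("+", scaled_matrix(pwm, eps)),
        ("-", scaled_matrix(pwm.reverse_complement(), eps)),
    ):
        scores = _window_lattice_scores(matrix, encoded)
        for pos in np.flatnonzero(scores >= thr):
            lattice = int(scores[pos])
            hits.append(
                MotifHit(pwm.motif_id, sequence_id, int(pos), strand,
                         lattice * eps, _lattice_pvalue(pwm, lattice, eps))
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def motif_edges_promoter(
    pwms_by_tf: Mapping[str, Sequence[PWM]],
    promoters: PromoterSet,
    p_threshold: float = 1e-4,
) -> set[tuple[str, str]]:
    """Directed (TF, gene) pairs with >= 1 motif hit of any of the TF's
    motifs in the gene's promoter. Promoters shorter than MIN_SCAN_LENGTH
    are skipped."""
    pairs: set[tuple[str, str]] = set()
    for gene, seq in promoters.sequences.items():
        if len(seq) < MIN_SCAN_LENGTH:
            logger.warning("promoter of %s shorter than %d bases; not scanned",
                           gene, MIN_SCAN_LENGTH)
            continue
        for tf, pwms in pwms_by_tf.items():
            if any(scan_sequence(p, seq, gene, p_threshold) for p in pwms):
                pairs.add((tf, gene))
    return pairs


def motif_edges_ocs(
    pwms_by_tf: Mapping[str, Sequence[PWM]],
    ocs: Sequence[GenomicInterval],
    genome: Mapping[str, str],
    genes: Mapping[str, GeneModel],
    p_threshold: float = 1e-4,
) -> set[tuple[str, str]]:
    """Scan open-chromatin sequences and map hit-bearing intervals to their
    closest gene(s); pair = (TF, assigned gene)."""
    seqs = extract_interval_sequences(ocs, genome)
    assignment = assign_intervals_to_genes(ocs, genes, mode="closest")
    keys = [iv.name or f"{iv.contig}:{iv.start}-{iv.end}" for iv in ocs]
    pairs: set[tuple[str, str]] = set()
    for iv, key in zip(ocs, keys):
        seq = seqs[key]
        targets = assignment[iv]
        if not targets:
            continue
        for tf, pwms in pwms_by_tf.items():
            if any(scan_sequence(p, seq, key, p_threshold) for p in pwms):
                pairs.update((tf, g) for g in targets)
    return pairs


# ---------------------------------------------------------------------------
# PFM I/O (JASPAR text and MEME minimal, via Biopython)
# ---------------------------------------------------------------------------

def read_pfms(path, fmt: str = "jaspar") -> list[PFM]:
    """Read PFMs from JASPAR text ('jaspar') or MEME minimal ('minimal').

    The TF id is taken from the motif name (JASPAR) or motif id; callers may
    re-map ids afterwards.
    """
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, fmt)
    out = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
        motif_id = getattr(m, "matrix_id", None) or m.name
        out.append(PFM(motif_id=motif_id, tf_id=m.name or motif_id, counts=counts))
    return out


def write_pfms_jaspar(pfms: Sequence[PFM], path) -> None:
    with open(path, "w") as fh:
        for p in pfms:
            fh.write(f">{p.motif_id} {p.tf_id}\n")
            for b, row in zip(BASES, p.counts):
                values = " ".join(f"{v:10.2f}" for v in row)
                fh.write(f"{b}  [{values} ]\n")
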