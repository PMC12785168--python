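"""Genomic data model and standard-format plumbing.

Internal coordinate convention is 0-based half-open throughout (BED-native);
GFF3 (1-based inclusive) is converted at the I/O boundary. Gene models are
gene-span level: the TSS of a gene is the 5' end of its annotated span.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("organgrn")

STRANDS = {"+", "-", "."}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a contig (BED semantics)."""

    contig: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class GeneModel:
    """Gene-span model; ``length`` is the base count used for TPM/FPKM."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    length: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span for {self.gene_id}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.length is not None and self.length < 1:
            raise ValueError(f"gene {self.gene_id}: length must be >= 1")

    @property
    def tss(self) -> int:
        """Strand-aware 5' end (0-based position of the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class PromoterSet:
    """Promoter sequences keyed by gene, oriented so the last base abuts the TSS."""

    sequences: dict[str, str]
    intervals: dict[str, GenomicInterval] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, gene_id: str) -> str:
        return self.sequences[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.sequences


#: finite vocabulary of TF-evidence source labels
TF_EVIDENCE_SOURCES = frozenset(
    {
        "annotation-keyword",
        "catalog-A",
        "catalog-B",
        "domain-scan",
        "GO-keyword",
        "ortholog",
    }
)


@dataclass
class TfEvidenceTable:
    """gene_id -> set of evidence-source labels from a declared vocabulary."""

    evidence: dict[str, set[str]]
    vocabulary: frozenset[str] = TF_EVIDENCE_SOURCES

    def __post_init__(self) -> None:
        for gene, sources in self.evidence.items():
            unknown = set(sources) - self.vocabulary
            if unknown:
                raise ValueError(f"gene {gene}: unknown evidence labels {sorted(unknown)}")


@dataclass
class RunConfig:
    """All pipeline constants in one place, loadable from YAML/JSON."""

    seeds: dict[str, int] = field(default_factory=lambda: {"inference": 123})
    tpm_threshold: float = 5.0
    tpm_fraction: float = 0.10
    fpkm_threshold: float = 0.5
    top_percent: float = 2.0
    top_percent_grid: tuple[float, ...] = (1, 2, 5, 8, 10)
    motif_p: float = 1e-4
    fdr: float = 0.05
    permutations: int = 1000
    gold_min_targets: int = 1000
    promoter_len: int = 2000
    dap_window: tuple[int, int] = (-2000, 500)
    ci_percentiles: tuple[float, float] = (2.5, 97.5)
    n_trees: int = 2000
    k_rule: str = "sqrt"
    log_level: str = "INFO"
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("tpm_threshold", "tpm_fraction", "fpkm_threshold", "top_percent",
                     "motif_p", "fdr", "permutations", "gold_min_targets",
                     "promoter_len", "n_trees"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.ci_percentiles
        if not lo < hi:
            raise ValueError("ci_percentiles must be ordered")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("top_percent_grid", "dap_window", "ci_percentiles"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_gff3_genes(path: str | Path) -> dict[str, GeneModel]:
    """Read gene features from GFF3 into 0-based half-open gene models."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, GeneModel] = {}
    for feat in db.features_of_type("gene"):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        genes[gene_id] = GeneModel(
            gene_id=gene_id,
            contig=feat.seqid,
            start=feat.start - 1,  # GFF3 is 1-based inclusive
            end=feat.end,
            strand=feat.strand,
        )
    return genes


def write_gff3_genes(genes: Mapping[str, GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.values():
            fh.write(
                f"{g.contig}\torgangrn\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED4+/narrowPeak; columns beyond strand are ignored."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
            strand = parts[5] if len(parts) > 5 and parts[5] in STRANDS else "."
            out.append(GenomicInterval(contig, start, end, strand, name, score))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t"
                f"{score}\t{iv.strand}\n"
            )


def read_evidence_table(path: str | Path) -> TfEvidenceTable:
    """TSV with columns gene_id<TAB>comma-separated evidence labels."""
    evidence: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            gene = parts[0]
            labels = {s for s in parts[1].split(",") if s} if len(parts) > 1 else set()
            evidence[gene] = labels
    return TfEvidenceTable(evidence)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def merge_gene_models(
    primary: Mapping[str, GeneModel], secondary: Mapping[str, GeneModel]
) -> dict[str, GeneModel]:
    """Coordinate-conditional merge: keep every primary gene, and add each
    secondary gene only when its span overlaps no primary gene span on the
    same contig (strand-ignorant, >=1 shared base)."""
    by_contig: dict[str, list[GeneModel]] = {}
    for g in primary.values():
        by_contig.setdefault(g.contig, []).append(g)

    merged = dict(primary)
    for gene_id in sorted(secondary):
        g = secondary[gene_id]
        overlapping = any(
            g.start < p.end and p.start < g.end for p in by_contig.get(g.contig, ())
        )
        if overlapping:
            continue
        if gene_id in merged:
            raise ValueError(f"duplicate gene_id after merge: {gene_id}")
        merged[gene_id] = g
    return merged


def classify_tfs(
    evidence: TfEvidenceTable,
    min_sources: int = 3,
    exclusion_list: set[str] | frozenset[str] = frozenset(),
) -> set[str]:
    """Genes supported by at least ``min_sources`` independent evidence
    sources, minus a manual-curation exclusion list."""
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    return {
        gene
        for gene, sources in evidence.evidence.items()
        if len(sources) >= min_sources and gene not in exclusion_list
    }


def extract_promoters(
    genes: Mapping[str, GeneModel],
    genome: Mapping[str, str],
    length: int = 2000,
) -> PromoterSet:
    """Sequences of the ``length`` bases upstream of each TSS, truncated at
    contig boundaries, reverse-complemented for minus-strand genes so the
    last base of the returned sequence abuts the TSS."""
    sequences: dict[str, str] = {}
    intervals: dict[str, GenomicInterval] = {}
    for gene_id in sorted(genes):
        g = genes[gene_id]
        if g.contig not in genome:
            raise KeyError(f"gene {gene_id}: contig {g.contig} missing from genome")
        contig_seq = genome[g.contig]
        if g.strand == "+":
            start, end = max(0, g.tss - length), g.tss
            seq = contig_seq[start:end]
        else:
            start = g.tss + 1
            end = min(len(contig_seq), g.tss + 1 + length)
            seq = reverse_complement(contig_seq[start:end])
        if start >= end:
            logger.warning("gene %s: zero-length promoter, omitted", gene_id)
            continue
        sequences[gene_id] = seq.upper()
        intervals[gene_id] = GenomicInterval(g.contig, start, end, g.strand, gene_id)
    return PromoterSet(sequences, intervals)


def _interval_gene_distance(iv: GenomicInterval, g: GeneModel) -> int:
    """Edge-to-edge genomic distance; 0 when the interval and span overlap."""
    if iv.start < g.end and g.start < iv.end:
        return 0
    if iv.end <= g.start:
        return g.start - iv.end
    return iv.start - g.end


def assign_intervals_to_genes(
    intervals: Sequence[GenomicInterval],
    genes: Mapping[str, GeneModel],
    mode: str = "closest",
    window: tuple[int, int] = (-2000, 500),
) -> dict[GenomicInterval, set[str]]:
    """Map each interval to candidate gene(s).

    ``closest``: the gene(s) minimising edge-to-edge distance on the same
    contig (all ties returned). ``tss_window``: genes whose strand-oriented
    window [tss+upstream, tss+downstream] contains the interval midpoint
    (the peak-to-gene rule used for in-vitro binding assignment).
    """
    if not genes:
        raise ValueError("assign_intervals_to_genes: gene set is empty")
    if mode not in {"closest", "tss_window"}:
        raise ValueError(f"unknown mode {mode!r}")
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes.values():
        by_contig.setdefault(g.contig, []).append(g)

    upstream, downstream = window
    result: dict[GenomicInterval, set[str]] = {}
    for iv in intervals:
        candidates = by_contig.get(iv.contig, [])
        assigned: set[str] = set()
        if mode == "closest":
            if candidates:
                dists = {g.gene_id: _interval_gene_distance(iv, g) for g in candidates}
                best = min(dists.values())
                assigned = {gid for gid, d in dists.items() if d == best}
        else:
            mid = iv.midpoint
            for g in candidates:
                rel = mid - g.tss if g.strand == "+" else g.tss - mid
                if upstream <= rel <= downstream:
                    assigned.add(g.gene_id)
        result[iv] = assigned
    return result


def extract_interval_sequences(
    intervals: Sequence[GenomicInterval], genome: Mapping[str, str]
) -> dict[str, str]:
    """Slice genome sequence for each interval (keyed by name or coordinates)."""
    out: dict[str, str] = {}
    for i, iv in enumerate(intervals):
        if iv.contig not in genome:
            raise KeyError(f"interval on unknown contig {iv.contig}")
        contig_seq = genome[iv.contig]
        if iv.end > len(contig_seq):
            raise ValueError(
                f"interval [{iv.start},{iv.end}) exceeds contig {iv.contig}"
            )
        key = iv.name or f"{iv.contig}:{iv.start}-{iv.end}"
        out[key] = contig_seq[iv.start:iv.end]
    return out
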