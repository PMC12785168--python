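"""Abundance normalisation and the expression filters that gate network input.

Expression matrices are plain pandas DataFrames (genes x samples) carried
alongside a per-sample metadata frame with ``organ`` and ``study`` columns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("organgrn")


@dataclass
class ExpressionMatrix:
    """genes x samples abundance table with organ/study sample metadata."""

    values: pd.DataFrame
    meta: pd.DataFrame  # index: sample_id; columns: organ, study
    unit: str = "arbitrary"  # counts | TPM | FPKM | arbitrary

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        missing = set(self.values.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        if "organ" not in self.meta.columns:
            raise ValueError("sample metadata must carry an 'organ' column")

    def subset_organ(self, organ: str) -> "ExpressionMatrix":
        samples = self.meta.index[self.meta["organ"] == organ]
        return ExpressionMatrix(self.values[samples], self.meta.loc[samples], self.unit)

    def subset_study(self, study: str) -> "ExpressionMatrix":
        samples = self.meta.index[self.meta["study"] == study]
        if len(samples) == 0:
            raise ValueError(f"study {study!r} has no samples")
        return ExpressionMatrix(self.values[samples], self.meta.loc[samples], self.unit)


@dataclass
class OrganExpressionSummary:
    expressed: dict[str, set[str]]
    organ_count: pd.Series = field(default_factory=pd.Series)
    organ_specific: set[str] = field(default_factory=set)
    class_histogram: pd.Series = field(default_factory=pd.Series)


def _check_lengths(counts: pd.DataFrame, lengths: pd.Series) -> pd.Series:
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"missing gene length for {missing[0]}")
    lengths = lengths.reindex(counts.index).astype(float)
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    return lengths


def counts_to_tpm(counts: pd.DataFrame, lengths: pd.Series,
                  meta: pd.DataFrame | None = None) -> pd.DataFrame | ExpressionMatrix:
    """Transcripts per million: length-rate normalisation so each sample's
    column sums to 1e6 (all-zero samples stay all-zero, with a warning)."""
    lengths = _check_lengths(counts, lengths)
    rate = counts.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("samples with zero total counts: %s", list(counts.columns[zero]))
        totals = totals.replace(0, np.nan)
    tpm = (rate.div(totals, axis=1) * 1e6).fillna(0.0)
    if meta is not None:
        return ExpressionMatrix(tpm, meta, unit="TPM")
    return tpm


def counts_to_fpkm(counts: pd.DataFrame, lengths: pd.Series,
                   meta: pd.DataFrame | None = None) -> pd.DataFrame | ExpressionMatrix:
    """Fragments per kilobase per million mapped reads."""
    lengths = _check_lengths(counts, lengths)
    libsize = counts.sum(axis=0)
    zero = libsize == 0
    if zero.any():
        logger.warning("samples with zero library size: %s", list(counts.columns[zero]))
        libsize = libsize.replace(0, np.nan)
    fpkm = (counts.div(libsize, axis=1).div(lengths, axis=0) * 1e9).fillna(0.0)
    if meta is not None:
        return ExpressionMatrix(fpkm, meta, unit="FPKM")
    return fpkm


def flag_expressed(tpm: pd.DataFrame, threshold: float = 5.0,
                   fraction: float = 0.10) -> set[str]:
    """Genes at >= ``threshold`` TPM in at least ``fraction`` of the samples
    (ceil rounding, so 'at least 10%' is literal for small sample counts)."""
    n = tpm.shape[1]
    if n == 0:
        raise ValueError("flag_expressed: no samples")
    need = math.ceil(fraction * n)
    hits = (tpm >= threshold).sum(axis=1)
    return set(tpm.index[hits >= need])


def expressed_by_organ(tpm: ExpressionMatrix, threshold: float = 5.0,
                       fraction: float = 0.10) -> dict[str, set[str]]:
    return {
        organ: flag_expressed(tpm.subset_organ(organ).values, threshold, fraction)
        for organ in sorted(tpm.meta["organ"].unique())
    }


def organ_specificity(sets: dict[str, set[str]]) -> OrganExpressionSummary:
    """Per-gene organ-count classes (1..n_organs) and the organ-specific set."""
    if not sets:
        raise ValueError("organ_specificity: empty organ mapping")
    all_genes = sorted(set().union(*sets.values()))
    counts = pd.Series(
        {g: sum(g in s for s in sets.values()) for g in all_genes}, dtype=int
    )
    histogram = counts.value_counts().sort_index()
    return OrganExpressionSummary(
        expressed=sets,
        organ_count=counts,
        organ_specific=set(counts.index[counts == 1]),
        class_histogram=histogram,
    )


def zscore_rows(table: pd.DataFrame) -> pd.DataFrame:
    """Row z-scaling with population (n) standard deviation; constant rows
    map to zero with a warning (heatmap-display semantics)."""
    mean = table.mean(axis=1)
    sd = table.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant rows z-scaled to zeros", int(constant.sum()))
        sd = sd.replace(0, np.nan)
    return table.sub(mean, axis=0).div(sd, axis=0).fillna(0.0)
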