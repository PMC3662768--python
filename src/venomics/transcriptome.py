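"""Contig ingest, assembly statistics, TPM quantification and expression filtering.

A de novo transcriptome assembly contains, besides genuine transcripts, a large
number of low-expression artifact contigs.  Quantifying expression in
transcripts-per-million (TPM) and dropping everything below a small threshold
(1 TPM by default) removes most artifacts while keeping expressed genes.

Quantification consumes a per-transcript read-count table rather than raw reads.
Counts may carry an optional ambiguity-group id: counts in a group cannot be
attributed to a single transcript and are split by an EM iteration proportional
to the current abundance estimates, the same fixed point a probabilistic
read-assignment quantifier converges to.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from ._util import percent

__all__ = [
    "Transcript",
    "AssemblyStats",
    "QuantConfig",
    "read_transcripts",
    "read_count_table",
    "assembly_stats",
    "n50",
    "estimate_tpm",
    "filter_expressed",
]


@dataclass
class Transcript:
    """A contig with its expression estimate."""

    id: str
    sequence: str
    read_count: float = 0.0
    tpm: float = 0.0

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AssemblyStats:
    n_transcripts_over_min: int
    n50: int
    mean_length: float


@dataclass
class QuantConfig:
    """Expression-filter and EM settings.

    tpm_threshold: transcripts at or above this TPM are kept (inclusive).
    min_report_length: assembly reports count transcripts strictly longer
        than this (bp).
    """

    tpm_threshold: float = 1.0
    min_report_length: int = 100
    em_max_iter: int = 200
    em_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if self.tpm_threshold < 0:
            raise ValueError("tpm_threshold must be >= 0")
        if self.em_tolerance <= 0:
            raise ValueError("em_tolerance must be > 0")


def read_transcripts(fasta: str | Path) -> list[Transcript]:
    """Read contigs from FASTA; ids must be unique, sequences non-empty."""
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(fasta), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate transcript id: {record.id}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for transcript {record.id}")
        seen.add(record.id)
        transcripts.append(Transcript(id=record.id, sequence=seq))
    return transcripts


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns transcript_id, length_bp, count[, ambiguity_group]."""
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    required = {"transcript_id", "length_bp", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if "ambiguity_group" not in df.columns:
        df["ambiguity_group"] = pd.NA
    return df


def n50(lengths: Sequence[int]) -> int:
    """Length L such that contigs of length >= L hold half the assembled bases.

    Computed by descending cumulative sum; the length reaching the half-total
    boundary is N50.  Empty input gives 0.
    """
    if len(lengths) == 0:
        return 0
    arr = np.sort(np.asarray(lengths))[::-1]
    half = arr.sum() / 2.0
    cum = np.cumsum(arr)
    return int(arr[np.searchsorted(cum, half, side="left")])


def assembly_stats(
    transcripts: Iterable[Transcript], min_report_length: int = 100
) -> AssemblyStats:
    lengths = [t.length for t in transcripts]
    if not lengths:
        return AssemblyStats(0, 0, 0.0)
    return AssemblyStats(
        n_transcripts_over_min=sum(1 for L in lengths if L > min_report_length),
        n50=n50(lengths),
        mean_length=float(np.mean(lengths)),
    )


def _em_split(
    counts: pd.DataFrame,
    lengths: dict[str, int],
    order: list[str],
    config: QuantConfig,
) -> np.ndarray:
    """Resolve ambiguity groups; returns per-transcript (possibly fractional) counts."""
    idx = {tid: i for i, tid in enumerate(order)}
    L = np.array([lengths[t] for t in order], dtype=float)
    unique = np.zeros(len(order))
    groups: list[tuple[float, np.ndarray]] = []
    grouped: dict[object, list[tuple[float, int]]] = {}
    for row in counts.itertuples(index=False):
        tid = row.transcript_id
        if tid not in idx:
            raise ValueError(f"count row references unknown transcript: {tid}")
        g = row.ambiguity_group
        if g is None or (isinstance(g, float) and math.isnan(g)) or g is pd.NA or g == "":
            unique[idx[tid]] += float(row.count)
        else:
            grouped.setdefault(g, []).append((float(row.count), idx[tid]))
    for members in grouped.values():
        total = sum(c for c, _ in members)
        groups.append((total, np.array([i for _, i in members], dtype=int)))

    c = unique.copy()
    for total, members in groups:  # equal split to start
        c[members] += total / len(members)
    if not groups:
        return c

    for _ in range(config.em_max_iter):
        rates = c / L
        c_new = unique.copy()
        for total, members in groups:
            w = rates[members]
            s = w.sum()
            if s <= 0:
                c_new[members] += total / len(members)
            else:
                c_new[members] += total * w / s
        denom = np.maximum(np.abs(c), 1e-300)
        rel = np.max(np.abs(c_new - c) / denom)
        c = c_new
        if rel < config.em_tolerance:
            break
    return c


def estimate_tpm(
    transcripts: list[Transcript],
    counts: pd.DataFrame,
    config: QuantConfig | None = None,
) -> list[Transcript]:
    """Set read_count and tpm on each transcript from the count table.

    tpm_i = (c_i / l_i) / sum_j (c_j / l_j) * 1e6 after EM resolution of any
    ambiguity groups.  All-zero counts leave every TPM at 0.
    """
    config = config or QuantConfig()
    order = [t.id for t in transcripts]
    lengths = {t.id: t.length for t in transcripts}
    c = _em_split(counts, lengths, order, config)
    L = np.array([t.length for t in transcripts], dtype=float)
    rates = c / L
    total = rates.sum()
    tpm = rates / total * 1e6 if total > 0 else np.zeros_like(rates)
    for t, ci, xi in zip(transcripts, c, tpm):
        t.read_count = float(ci)
        t.tpm = float(xi)
    return transcripts


def filter_expressed(
    transcripts: Iterable[Transcript], tpm_threshold: float = 1.0
) -> tuple[list[Transcript], list[Transcript]]:
    """Partition into (kept, removed) by tpm >= threshold (inclusive)."""
    kept, removed = [], []
    for t in transcripts:
        (kept if t.tpm >= tpm_threshold else removed).append(t)
    return kept, removed


def retention_percent(n_kept: int, n_initial: int) -> int:
    """Integer retention percentage as printed in assembly/proteomics reports."""
    return percent(n_kept, n_initial)
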