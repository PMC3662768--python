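"""Validation statistics for a putative venom-protein set.

Three independent lines of evidence support a venom call: secreted proteins
should carry N-terminal secretion signals far more often than body proteins
(2x2 chi-square); venom transcripts should resemble known venoms more closely
than body transcripts (binned best-hit E-value distributions compared by
chi-square); and conserved-domain repertoires can be compared across sets
(three-way Venn counts).

Secretion signals are called by a transparent three-part heuristic over the
classical signal-peptide architecture — a positively charged n-region, a
hydrophobic h-region and a small-residue (-3, -1) cleavage site — rather than
a trained predictor; predictions from an external tool can be imported from
TSV and substituted without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from ._util import percent

__all__ = [
    "KYTE_DOOLITTLE",
    "SignalPrediction",
    "ChiSquareResult",
    "BinnedEvalueDistribution",
    "predict_signal",
    "load_signal_predictions",
    "signal_enrichment",
    "bin_evalues",
    "compare_distributions",
    "domain_overlap",
    "read_blast_tabular",
    "best_hits",
    "DEFAULT_EVALUE_EDGES",
]

KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9, "R": -4.5,
}

_SMALL = frozenset("AGSCT")  # permitted at the -3 and -1 cleavage positions
_BASIC = frozenset("KR")


@dataclass(frozen=True)
class SignalPrediction:
    protein_id: str
    call: bool
    score: float
    cleavage_position: int | None  # 1-based length of the signal peptide


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class BinnedEvalueDistribution:
    label: str
    bin_edges: tuple[float, ...]  # powers of ten, most significant first
    counts: tuple[int, ...]  # len(bin_edges) + 1


def _best_hydropathy_window(seq: str, lo: int, hi: int, width: int = 8) -> float:
    """Best mean Kyte-Doolittle hydropathy over width-residue windows fully
    inside 1-based residues [lo, hi]."""
    best = float("-inf")
    for start in range(lo - 1, min(hi, len(seq)) - width + 1):
        window = seq[start : start + width]
        if len(window) < width:
            break
        best = max(best, sum(KYTE_DOOLITTLE.get(a, 0.0) for a in window) / width)
    return best


def predict_signal(sequence: str, protein_id: str = "") -> SignalPrediction:
    """Heuristic secretion-signal call on an N-terminal amino-acid sequence.

    call is true when all three hold: a K/R among residues 1-5 (charged
    n-region); an 8-residue window within residues 6-25 with mean
    Kyte-Doolittle hydropathy >= 1.5 (hydrophobic h-region); and a cleavage
    position in residues 15-35 whose -3 and -1 residues are small
    (A/G/S/C/T).  Sequences shorter than 15 residues are never called.
    """
    seq = sequence.upper()
    score = _best_hydropathy_window(seq, 6, 25)
    if len(seq) < 15:
        return SignalPrediction(protein_id, False, score, None)
    n_region = any(a in _BASIC for a in seq[:5])
    h_region = score >= 1.5
    cleavage = None
    for c in range(15, min(35, len(seq)) + 1):  # c = last residue of the signal
        if seq[c - 1] in _SMALL and seq[c - 3] in _SMALL:
            cleavage = c
            break
    call = n_region and h_region and cleavage is not None
    return SignalPrediction(protein_id, call, score, cleavage if call else None)


def load_signal_predictions(path: str | Path) -> dict[str, SignalPrediction]:
    """Import external predictions from TSV (protein_id, call, position)."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for r in df.itertuples(index=False):
        call = bool(r.call) if not isinstance(r.call, str) else r.call.lower() in (
            "true", "yes", "y", "1",
        )
        pos = None if pd.isna(r.position) else int(r.position)
        out[str(r.protein_id)] = SignalPrediction(str(r.protein_id), call, float("nan"), pos)
    return out


def signal_enrichment(
    venom: tuple[int, int], comparison: tuple[int, int]
) -> tuple[ChiSquareResult, int, int]:
    """2x2 chi-square of signal presence vs group (no continuity correction).

    venom/comparison are (with-signal, total).  Returns the test result plus
    the two proportions as integer percentages.
    """
    (k1, n1), (k2, n2) = venom, comparison
    if n1 <= 0 or n2 <= 0 or not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n with n > 0")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if (table.sum(axis=0) == 0).any():
        raise ValueError("chi-square undefined: a column marginal is zero")
    stat, p, df, _ = chi2_contingency(table, correction=False)
    return ChiSquareResult(float(stat), int(df), float(p)), percent(k1, n1), percent(k2, n2)


DEFAULT_EVALUE_EDGES = (1e-100, 1e-50, 1e-20, 1e-10, 1e-5, 1e-2, 1.0)


def bin_evalues(
    evalues: Iterable[float],
    bin_edges: Sequence[float] = DEFAULT_EVALUE_EDGES,
    label: str = "",
) -> BinnedEvalueDistribution:
    """Histogram E-values into significance bins.

    With edges e_1 < ... < e_B, bin 0 holds values <= e_1, bin i holds
    (e_i, e_{i+1}], and the last bin holds values > e_B; a value exactly on an
    edge falls in the lower (more significant) bin.
    """
    edges = sorted(float(e) for e in bin_edges)
    vals = np.asarray(list(evalues), dtype=float)
    if (vals < 0).any():
        raise ValueError("E-values must be >= 0")
    idx = np.searchsorted(edges, vals, side="left")
    counts = np.bincount(idx, minlength=len(edges) + 1)
    return BinnedEvalueDistribution(label, tuple(edges), tuple(int(c) for c in counts))


def compare_distributions(
    a: BinnedEvalueDistribution, b: BinnedEvalueDistribution
) -> ChiSquareResult:
    """Chi-square homogeneity test of two binned E-value distributions.

    Bins empty in both distributions are collapsed away; df = B' - 1 over the
    B' remaining bins.
    """
    if a.bin_edges != b.bin_edges:
        raise ValueError("distributions use different bin edges")
    table = np.array([a.counts, b.counts])
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        raise ValueError("chi-square undefined with fewer than 2 nonempty bins")
    stat, p, df, _ = chi2_contingency(table, correction=False)
    return ChiSquareResult(float(stat), int(df), float(p))


def domain_overlap(
    set_a: Iterable[str], set_b: Iterable[str], set_c: Iterable[str]
) -> dict[str, int]:
    """Exclusive-region counts of a three-set Venn diagram."""
    A, B, C = set(set_a), set(set_b), set(set_c)
    return {
        "A_only": len(A - B - C),
        "B_only": len(B - A - C),
        "C_only": len(C - A - B),
        "AB_only": len((A & B) - C),
        "AC_only": len((A & C) - B),
        "BC_only": len((B & C) - A),
        "ABC": len(A & B & C),
    }


_BLAST_COLUMNS = [
    "query", "subject", "identity", "length", "mismatches", "gapopens",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_blast_tabular(path: str | Path) -> pd.DataFrame:
    """Read 12-column tabular BLAST output (outfmt 6)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != 12:
        raise ValueError(f"expected 12 tabular columns, got {df.shape[1]}")
    df.columns = _BLAST_COLUMNS
    return df


def best_hits(blast: pd.DataFrame) -> pd.DataFrame:
    """Single best hit per query: lowest E-value, ties by highest bitscore."""
    df = blast.sort_values(
        ["query", "evalue", "bitscore"], ascending=[True, True, False], kind="mergesort"
    )
    return df.drop_duplicates("query", keep="first").reset_index(drop=True)
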