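"""Peptide filtering, mapping into the translated database, and protein inference.

The identification cascade mirrors standard shotgun-proteomics quality control:
peptides must be longer than 4 residues, have probability above 0.5 and a charge
other than +1; a transcript is promoted to a venom-protein identification only
when it retains at least two distinct peptides and its aggregated protein
probability exceeds 0.7.  Shared peptides are resolved by razor assignment to
the transcript with the strongest independent evidence, so every retained
peptide counts toward exactly one protein.

Matching treats isoleucine and leucine as identical by default: they are
isobaric and indistinguishable to the mass spectrometer.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from ._util import percent
from .translation import OrfSegment

__all__ = [
    "PeptideObservation",
    "FilterConfig",
    "PeptideMatch",
    "ProteinIdentification",
    "read_peptide_table",
    "filter_peptides",
    "map_peptides",
    "infer_proteins",
    "coverage_fraction",
    "spectral_summary",
]


@dataclass(frozen=True)
class PeptideObservation:
    sequence: str
    probability: float
    charge: int
    spectral_count: int = 1

    def __post_init__(self) -> None:
        if not self.sequence or "*" in self.sequence:
            raise ValueError("peptide sequence must be nonempty and stop-free")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("peptide probability must lie in [0, 1]")
        if self.charge < 1 or self.spectral_count < 1:
            raise ValueError("charge and spectral_count must be positive")


@dataclass
class FilterConfig:
    """Identification thresholds; length/probability cut-offs are strict (>)."""

    min_peptide_len_exclusive: int = 4
    min_peptide_prob_exclusive: float = 0.5
    excluded_charges: frozenset[int] = frozenset({1})
    min_peptides_per_protein: int = 2
    min_protein_prob_exclusive: float = 0.7
    il_equivalence: bool = True


@dataclass(frozen=True)
class PeptideMatch:
    peptide: str  # canonical (I/L-collapsed) sequence
    transcript_id: str
    frame: int
    orf: OrfSegment
    aa_start: int  # within the OrfSegment
    unique_flag: bool  # True iff the peptide matches exactly one transcript


@dataclass
class ProteinIdentification:
    transcript_id: str
    orf: OrfSegment  # representative ORF (coverage denominator)
    distinct_peptides: int
    total_spectral_count: int
    protein_probability: float
    coverage: float
    normalized_spectral_abundance: float = 0.0
    peptides: tuple[str, ...] = ()


def read_peptide_table(path: str | Path) -> list[PeptideObservation]:
    """Read a TSV with columns sequence, probability, charge, spectral_count."""
    df = pd.read_csv(path, sep="\t")
    required = {"sequence", "probability", "charge", "spectral_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peptide table missing columns: {sorted(missing)}")
    return [
        PeptideObservation(
            sequence=str(r.sequence).upper(),
            probability=float(r.probability),
            charge=int(r.charge),
            spectral_count=int(r.spectral_count),
        )
        for r in df.itertuples(index=False)
    ]


def filter_peptides(
    observations: Iterable[PeptideObservation], config: FilterConfig | None = None
) -> list[PeptideObservation]:
    """Keep peptides with length > 4, probability > 0.5 and allowed charge."""
    config = config or FilterConfig()
    return [
        o
        for o in observations
        if len(o.sequence) > config.min_peptide_len_exclusive
        and o.probability > config.min_peptide_prob_exclusive
        and o.charge not in config.excluded_charges
    ]


def _canonical(seq: str, il_equivalence: bool) -> str:
    return seq.replace("L", "I") if il_equivalence else seq


def map_peptides(
    observations: Sequence[PeptideObservation],
    orfs: Sequence[OrfSegment],
    il_equivalence: bool = True,
) -> tuple[list[PeptideMatch], list[PeptideObservation]]:
    """Exact substring search of every peptide against every search ORF.

    All placements are reported; unique_flag marks peptides whose placements
    fall within a single transcript (multiple placements inside one transcript
    still count as one transcript hit).  Returns (matches, unmatched
    observations).
    """
    # One concatenated haystack with '#' separators keeps the search in C code.
    canon_orfs = [_canonical(o.sequence, il_equivalence) for o in orfs]
    haystack = "#" + "#".join(canon_orfs) + "#"
    starts = []  # global offset of each ORF within the haystack
    pos = 1
    for s in canon_orfs:
        starts.append(pos)
        pos += len(s) + 1

    placements: dict[str, list[tuple[int, int]]] = {}
    for seq in {_canonical(o.sequence, il_equivalence) for o in observations}:
        hits = []
        i = haystack.find(seq)
        while i != -1:
            oi = bisect_right(starts, i) - 1
            hits.append((oi, i - starts[oi]))
            i = haystack.find(seq, i + 1)
        if hits:
            placements[seq] = hits

    matches: list[PeptideMatch] = []
    for seq, hits in placements.items():
        n_transcripts = len({orfs[oi].transcript_id for oi, _ in hits})
        for oi, aa_start in hits:
            seg = orfs[oi]
            matches.append(
                PeptideMatch(
                    peptide=seq,
                    transcript_id=seg.transcript_id,
                    frame=seg.frame,
                    orf=seg,
                    aa_start=aa_start,
                    unique_flag=n_transcripts == 1,
                )
            )
    unmatched = [
        o
        for o in observations
        if _canonical(o.sequence, il_equivalence) not in placements
    ]
    return matches, unmatched


def coverage_fraction(
    intervals: Iterable[tuple[int, int]], orf_length: int
) -> float:
    """Fraction of ORF residues covered by the union of half-open aa intervals."""
    ivs = sorted((max(0, a), min(orf_length, b)) for a, b in intervals)
    covered = 0
    cur_a: int | None = None
    cur_b = 0
    for a, b in ivs:
        if a >= b:
            continue
        if cur_a is None or a > cur_b:
            if cur_a is not None:
                covered += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    if cur_a is not None:
        covered += cur_b - cur_a
    return covered / orf_length if orf_length > 0 else 0.0


def infer_proteins(
    matches: Sequence[PeptideMatch],
    observations: Sequence[PeptideObservation],
    config: FilterConfig | None = None,
) -> list[ProteinIdentification]:
    """Razor-resolve shared peptides and promote well-supported transcripts.

    Per distinct (I/L-collapsed) peptide sequence, the probability entering the
    protein-probability product is the best observation of that sequence and
    spectral counts are summed over observations.  A shared peptide is assigned
    to the candidate transcript with the highest current distinct-peptide
    count, breaking ties by higher current spectral count then lexicographic
    transcript id.  Identification requires >= 2 retained distinct peptides and
    protein probability 1 - prod(1 - p_i) > 0.7.
    """
    config = config or FilterConfig()

    # distinct-peptide evidence
    prob: dict[str, float] = {}
    spc: dict[str, int] = {}
    for o in observations:
        seq = _canonical(o.sequence, config.il_equivalence)
        prob[seq] = max(prob.get(seq, 0.0), o.probability)
        spc[seq] = spc.get(seq, 0) + o.spectral_count

    pep_transcripts: dict[str, set[str]] = {}
    pep_placements: dict[str, list[PeptideMatch]] = {}
    for m in matches:
        pep_transcripts.setdefault(m.peptide, set()).add(m.transcript_id)
        pep_placements.setdefault(m.peptide, []).append(m)

    assigned: dict[str, list[str]] = {}  # transcript -> peptide seqs
    tr_spc: dict[str, int] = {}

    def _assign(seq: str, tid: str) -> None:
        assigned.setdefault(tid, []).append(seq)
        tr_spc[tid] = tr_spc.get(tid, 0) + spc.get(seq, 0)

    shared = []
    for seq in sorted(pep_transcripts):
        tids = pep_transcripts[seq]
        if len(tids) == 1:
            _assign(seq, next(iter(tids)))
        else:
            shared.append(seq)
    for seq in shared:  # razor: strongest current evidence wins
        tid = min(
            pep_transcripts[seq],
            key=lambda t: (-len(assigned.get(t, [])), -tr_spc.get(t, 0), t),
        )
        _assign(seq, tid)

    identifications: list[ProteinIdentification] = []
    for tid in sorted(assigned):
        peptides = assigned[tid]
        if len(peptides) < config.min_peptides_per_protein:
            continue
        p = 1.0
        for seq in peptides:
            p *= 1.0 - prob.get(seq, 0.0)
        protein_prob = 1.0 - p
        if protein_prob <= config.min_protein_prob_exclusive:
            continue

        # representative ORF: most retained-peptide placements, ties -> longest
        by_orf: dict[OrfSegment, list[PeptideMatch]] = {}
        for seq in peptides:
            for m in pep_placements[seq]:
                if m.transcript_id == tid:
                    by_orf.setdefault(m.orf, []).append(m)
        rep = max(by_orf, key=lambda o: (len(by_orf[o]), len(o)))
        cov = coverage_fraction(
            [(m.aa_start, m.aa_start + len(m.peptide)) for m in by_orf[rep]],
            len(rep),
        )
        identifications.append(
            ProteinIdentification(
                transcript_id=tid,
                orf=rep,
                distinct_peptides=len(peptides),
                total_spectral_count=sum(spc.get(s, 0) for s in peptides),
                protein_probability=protein_prob,
                coverage=cov,
                peptides=tuple(sorted(peptides)),
            )
        )

    # normalized spectral abundance: length-corrected counts summing to 1
    weights = [i.total_spectral_count / len(i.orf) for i in identifications]
    total = sum(weights)
    if total > 0:
        for ident, w in zip(identifications, weights):
            ident.normalized_spectral_abundance = w / total
    return identifications


def spectral_summary(
    identifications: Sequence[ProteinIdentification],
    n_initial_peptides: int | None = None,
    n_filtered_peptides: int | None = None,
) -> dict:
    """Global summary mirroring a proteomics results table."""
    out: dict = {"n_proteins": len(identifications)}
    if identifications:
        out["mean_peptide_hits"] = sum(
            i.distinct_peptides for i in identifications
        ) / len(identifications)
        out["mean_coverage_pct"] = (
            100.0 * sum(i.coverage for i in identifications) / len(identifications)
        )
    if n_initial_peptides and n_filtered_peptides is not None:
        out["peptide_retention_pct"] = percent(n_filtered_peptides, n_initial_peptides)
    return out


def identifications_table(
    identifications: Sequence[ProteinIdentification],
) -> pd.DataFrame:
    rows = [
        {
            "transcript_id": i.transcript_id,
            "frame": i.orf.frame,
            "orf_aa_start": i.orf.aa_start,
            "orf_length": len(i.orf),
            "distinct_peptides": i.distinct_peptides,
            "total_spectral_count": i.total_spectral_count,
            "normalized_spectral_abundance": i.normalized_spectral_abundance,
            "protein_probability": i.protein_probability,
            "coverage": i.coverage,
        }
        for i in identifications
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id",
            "frame",
            "orf_aa_start",
            "orf_length",
            "distinct_peptides",
            "total_spectral_count",
            "normalized_spectral_abundance",
            "protein_probability",
            "coverage",
        ],
    )
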