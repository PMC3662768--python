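"""Six-frame translation and ORF extraction for the peptide-search database.

Without gene models, the search space for peptide matching is every transcript
translated in all three frames on both strands.  Search ORFs are maximal
stop-free runs (stop-to-stop; no start-codon requirement) because tryptic
peptides can fall anywhere inside a coding region and cannot span a stop.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import reverse_complement

__all__ = [
    "FRAMES",
    "FrameTranslation",
    "OrfSegment",
    "six_frame_translate",
    "extract_orfs",
    "longest_orf",
    "build_search_database",
    "write_orf_fasta",
]

FRAMES = (1, 2, 3, -1, -2, -3)

# Standard genetic code (table 1); stops rendered '*'.  A codon containing any
# non-ACGT base translates to 'X' even when the ambiguity would resolve.
_CODON: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON[_stop] = "*"


@dataclass(frozen=True)
class FrameTranslation:
    transcript_id: str
    frame: int  # one of +-1, +-2, +-3
    aa_sequence: str
    nt_offset: int  # 0-based start offset on the translated strand


@dataclass(frozen=True)
class OrfSegment:
    transcript_id: str
    frame: int
    aa_start: int  # 0-based half-open within the frame translation
    aa_end: int
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


def _translate(nt: str) -> str:
    aas = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i : i + 3]
        aas.append(_CODON.get(codon, "X"))
    return "".join(aas)


def six_frame_translate(transcript_id: str, sequence: str) -> list[FrameTranslation]:
    """Translate in frames +1..+3 (forward) and -1..-3 (reverse complement)."""
    seq = sequence.upper()
    rc = reverse_complement(seq)
    out = []
    for frame in FRAMES:
        strand = seq if frame > 0 else rc
        offset = abs(frame) - 1
        out.append(
            FrameTranslation(
                transcript_id=transcript_id,
                frame=frame,
                aa_sequence=_translate(strand[offset:]),
                nt_offset=offset,
            )
        )
    return out


def extract_orfs(ft: FrameTranslation, min_aa_len: int = 1) -> list[OrfSegment]:
    """Maximal stop-free runs of length >= min_aa_len, in frame-local coordinates."""
    if min_aa_len < 1:
        raise ValueError("min_aa_len must be >= 1")
    segments = []
    start = None
    aa = ft.aa_sequence
    for i, ch in enumerate(aa + "*"):  # sentinel stop flushes the last run
        if ch == "*":
            if start is not None and i - start >= min_aa_len:
                segments.append(
                    OrfSegment(ft.transcript_id, ft.frame, start, i, aa[start:i])
                )
            start = None
        elif start is None:
            start = i
    return segments


def longest_orf(transcript_id: str, sequence: str) -> OrfSegment | None:
    """Longest stop-free ORF across all six frames.

    Ties resolved by frame order +1, +2, +3, -1, -2, -3, then smallest aa_start.
    Returns None when no ORF of at least 1 aa exists.
    """
    best: OrfSegment | None = None
    for ft in six_frame_translate(transcript_id, sequence):
        for seg in extract_orfs(ft, 1):
            if best is None or len(seg) > len(best):
                best = seg
    return best


def build_search_database(
    transcripts: Iterable, min_aa_len: int = 5
) -> list[OrfSegment]:
    """All search ORFs over a transcript set (objects with .id and .sequence)."""
    orfs: list[OrfSegment] = []
    for t in transcripts:
        for ft in six_frame_translate(t.id, t.sequence):
            orfs.extend(extract_orfs(ft, min_aa_len))
    return orfs


def write_orf_fasta(orfs: Iterable[OrfSegment], path: str | Path) -> None:
    """Write the search database; headers are transcript_id|frame|aa_start."""
    with open(path, "w") as fh:
        for seg in orfs:
            fh.write(f">{seg.transcript_id}|{seg.frame:+d}|{seg.aa_start}\n")
            fh.write(seg.sequence + "\n")
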