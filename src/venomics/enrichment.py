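"""GO-term over-representation of the venom set against the expressed population.

Annotations arrive either as a direct gene -> term map or as the composition of
a gene -> protein-family table with a family -> GO translation table.  Each
term with at least one annotated gene in the population is tested with the
one-sided hypergeometric upper tail; Bonferroni correction multiplies by the
number of tested terms.  The GO hierarchy is not propagated: terms are compared
exactly as given by the flat translation table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from ._util import percent

__all__ = [
    "EnrichmentResult",
    "load_annotations",
    "load_annotation_map",
    "annotation_summary",
    "enrich",
]

AnnotationMap = dict[str, set[str]]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    study_count: int
    study_size: int
    population_count: int
    population_size: int
    p_raw: float
    p_bonferroni: float
    significant: bool


def _read_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV; the second column may be a ';'-separated list."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: malformed row at line {lineno}")
            left, right = fields
            for item in right.split(";"):
                item = item.strip()
                if item:
                    pairs.append((left, item))
            if not right.strip():
                pairs.append((left, ""))
    return pairs


def load_annotations(
    gene_family_tsv: str | Path, family_term_tsv: str | Path
) -> AnnotationMap:
    """Compose gene -> family and family -> term tables into gene -> terms.

    Genes whose families have no term translation get empty sets.
    """
    fam_terms: dict[str, set[str]] = {}
    for fam, term in _read_pairs(family_term_tsv):
        if term:
            fam_terms.setdefault(fam, set()).add(term)
    annot: AnnotationMap = {}
    for gene, fam in _read_pairs(gene_family_tsv):
        annot.setdefault(gene, set())
        if fam:
            annot[gene] |= fam_terms.get(fam, set())
    return annot


def load_annotation_map(path: str | Path) -> AnnotationMap:
    """Direct gene -> terms TSV (gene_id <tab> term;term;...)."""
    annot: AnnotationMap = {}
    for gene, term in _read_pairs(path):
        annot.setdefault(gene, set())
        if term:
            annot[gene].add(term)
    return annot


def annotation_summary(genes: Iterable[str], annot: AnnotationMap) -> dict:
    """Fraction of genes with any annotation, as count pair plus percentage."""
    genes = list(genes)
    annotated = sum(1 for g in genes if annot.get(g))
    return {
        "annotated": annotated,
        "total": len(genes),
        "pct": percent(annotated, len(genes)) if genes else 0,
    }


def enrich(
    study: Iterable[str],
    population: Iterable[str],
    annot: Mapping[str, set[str]],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One-sided hypergeometric over-representation with Bonferroni correction.

    For each term with population count K >= 1, p_raw = P(X >= k) with
    X ~ Hypergeom(N, K, n); p_bonferroni = min(1, p_raw * m) over the m tested
    terms.  Results are sorted by ascending p_raw.
    """
    study_set, pop_set = set(study), set(population)
    if not pop_set:
        raise ValueError("population must be nonempty")
    if not study_set <= pop_set:
        raise ValueError("study set must be a subset of the population")
    N, n = len(pop_set), len(study_set)

    pop_count: dict[str, int] = {}
    study_count: dict[str, int] = {}
    for g in pop_set:
        for t in annot.get(g, ()):
            pop_count[t] = pop_count.get(t, 0) + 1
            if g in study_set:
                study_count[t] = study_count.get(t, 0) + 1
    m = len(pop_count)

    results = []
    for term, K in pop_count.items():
        k = study_count.get(term, 0)
        p_raw = float(hypergeom.sf(k - 1, N, K, n))
        p_bonf = min(1.0, p_raw * m)
        results.append(
            EnrichmentResult(
                term_id=term,
                study_count=k,
                study_size=n,
                population_count=K,
                population_size=N,
                p_raw=p_raw,
                p_bonferroni=p_bonf,
                significant=p_bonf < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_raw, r.term_id))
    return results


def results_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
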