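"""End-to-end orchestration: quantify -> filter -> translate -> map -> infer ->
validate -> enrich, with a self-consistent report.

Every percentage in the report sits next to the numerator/denominator pair it
was computed from, so the report can be audited like the published summary
tables it mirrors.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from ._util import percent
from .enrichment import AnnotationMap, enrich, results_table
from .peptide_id import (
    FilterConfig,
    PeptideObservation,
    filter_peptides,
    identifications_table,
    infer_proteins,
    map_peptides,
    spectral_summary,
)
from .synthetic import ScenarioConfig, generate_scenario
from .transcriptome import (
    QuantConfig,
    Transcript,
    assembly_stats,
    estimate_tpm,
    filter_expressed,
)
from .translation import OrfSegment, build_search_database
from .validation import predict_signal, signal_enrichment

__all__ = ["run_pipeline", "run_scenario", "extrapolate_true_positives"]


def extrapolate_true_positives(
    identified_count: int, validated_positive: int, validated_total: int
) -> int:
    """Scale an identification count by an independently validated true-positive
    rate, truncating to an integer: floor(identified * positive / total)."""
    if validated_total <= 0:
        raise ValueError("validated_total must be > 0")
    return (identified_count * validated_positive) // validated_total


def _ratio(num: int, den: int) -> dict:
    return {"num": int(num), "den": int(den), "pct": percent(num, den) if den else 0}


def _longest_per_transcript(orfs: list[OrfSegment]) -> dict[str, OrfSegment]:
    best: dict[str, OrfSegment] = {}
    for seg in orfs:
        cur = best.get(seg.transcript_id)
        if cur is None or len(seg) > len(cur):
            best[seg.transcript_id] = seg
    return best


def run_pipeline(
    transcripts: list[Transcript],
    counts: pd.DataFrame,
    observations: list[PeptideObservation],
    annotations: AnnotationMap | None = None,
    *,
    quant: QuantConfig | None = None,
    filters: FilterConfig | None = None,
    alpha: float = 0.05,
    body_is_all: bool = False,
    search_min_aa_len: int = 5,
    truth=None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run every stage on in-memory inputs and return the audit report.

    body_is_all controls the secretion-signal comparison set: the full
    expressed set (True) or the expressed set minus identified venom proteins
    (False, default).  When a ScenarioTruth is supplied the report gains
    sensitivity/precision against the planted venom set and the recovery
    status of each planted enriched GO term.
    """
    quant = quant or QuantConfig()
    filters = filters or FilterConfig()

    initial_stats = assembly_stats(transcripts, quant.min_report_length)
    estimate_tpm(transcripts, counts, quant)
    kept, removed = filter_expressed(transcripts, quant.tpm_threshold)
    filtered_stats = assembly_stats(kept, quant.min_report_length)

    orfs = build_search_database(kept, search_min_aa_len)
    kept_obs = filter_peptides(observations, filters)
    matches, unmatched = map_peptides(kept_obs, orfs, filters.il_equivalence)
    identifications = infer_proteins(matches, kept_obs, filters)
    summary = spectral_summary(identifications, len(observations), len(kept_obs))

    identified_ids = {i.transcript_id for i in identifications}
    longest = _longest_per_transcript(orfs)
    venom_calls = [
        predict_signal(longest[t].sequence, t) for t in sorted(identified_ids)
        if t in longest
    ]
    if body_is_all:
        comparison_ids = sorted(longest)
    else:
        comparison_ids = sorted(set(longest) - identified_ids)
    body_calls = [predict_signal(longest[t].sequence, t) for t in comparison_ids]
    k1 = sum(c.call for c in venom_calls)
    k2 = sum(c.call for c in body_calls)
    signals: dict = {
        "venom": _ratio(k1, len(venom_calls)),
        "comparison": _ratio(k2, len(body_calls)),
        "comparison_is_all": body_is_all,
    }
    if venom_calls and body_calls:
        try:
            chi, _, _ = signal_enrichment((k1, len(venom_calls)), (k2, len(body_calls)))
            signals["chi_square"] = {
                "statistic": chi.statistic, "df": chi.df, "p_value": chi.p_value,
            }
        except ValueError as exc:  # zero marginal
            signals["chi_square"] = {"undefined": str(exc)}

    enrichment_results = []
    if annotations is not None and identified_ids:
        population = [t.id for t in kept]
        enrichment_results = enrich(
            sorted(identified_ids), population, annotations, alpha
        )

    report: dict = {
        "provenance": {"tool": "venomics", "version": __version__},
        "assembly": {
            "initial": asdict(initial_stats),
            "filtered": asdict(filtered_stats),
            "retention": _ratio(len(kept), len(transcripts)),
            "tpm_threshold": quant.tpm_threshold,
        },
        "peptides": {
            "initial": len(observations),
            "filtered": len(kept_obs),
            "retention": _ratio(len(kept_obs), len(observations))
            if observations
            else _ratio(0, 0),
            "unmatched": len(unmatched),
        },
        "identifications": {
            "count": len(identifications),
            "mean_peptide_hits": summary.get("mean_peptide_hits"),
            "mean_coverage_pct": summary.get("mean_coverage_pct"),
        },
        "signals": signals,
        "enrichment": {
            "n_terms_tested": len(enrichment_results),
            "significant_terms": [
                r.term_id for r in enrichment_results if r.significant
            ],
            "alpha": alpha,
        },
    }

    if truth is not None:
        venom_true = truth.venom_ids()
        tp = len(identified_ids & venom_true)
        report["truth"] = {
            "sensitivity": tp / len(venom_true) if venom_true else None,
            "precision": tp / len(identified_ids) if identified_ids else None,
            "planted_enriched_terms": list(truth.enriched_terms),
            "recovered_enriched_terms": [
                t
                for t in truth.enriched_terms
                if t in report["enrichment"]["significant_terms"]
            ],
        }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        identifications_table(identifications).to_csv(
            out / "identifications.tsv", sep="\t", index=False, float_format="%.6g"
        )
        if enrichment_results:
            results_table(enrichment_results).to_csv(
                out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g"
            )
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)

    report["_objects"] = {
        "identifications": identifications,
        "enrichment_results": enrichment_results,
        "kept_transcripts": kept,
        "removed_transcripts": removed,
        "matches": matches,
    }
    return report


def run_scenario(
    config: ScenarioConfig | None = None,
    *,
    quant: QuantConfig | None = None,
    filters: FilterConfig | None = None,
    alpha: float = 0.05,
    body_is_all: bool = False,
    out_dir: str | Path | None = None,
) -> dict:
    """Generate a synthetic scenario and run the full pipeline on it."""
    scenario = generate_scenario(config)
    return run_pipeline(
        [Transcript(tid, seq) for tid, seq in scenario.transcripts],
        scenario.counts,
        [
            PeptideObservation(r.sequence, r.probability, int(r.charge), int(r.spectral_count))
            for r in scenario.peptides.itertuples(index=False)
        ],
        annotations={g: set(ts) for g, ts in scenario.go_map.items()},
        quant=quant,
        filters=filters,
        alpha=alpha,
        body_is_all=body_is_all,
        truth=scenario.truth,
        out_dir=out_dir,
    )
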