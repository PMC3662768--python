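"""Ground-truthed synthetic scenarios for the venom-identification pipeline.

A scenario emulates the statistical structure of a venom-gland proteogenomics
experiment at desk scale: an abdomen transcriptome containing expressed body
genes, a small set of highly expressed venom genes whose proteins dominate the
identified-peptide pool, and a large tail of low-expression assembly artifact
contigs; tryptic peptides sampled from the venom proteins plus a contaminant
fraction; planted N-terminal secretion signals at a high rate in venom and a
low rate in body proteins; and GO annotations with a few terms planted as
venom-enriched.

Everything is drawn from a single seeded generator in a fixed order, so a
scenario is byte-identical across runs with the same configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "ScenarioConfig",
    "ScenarioTruth",
    "Scenario",
    "in_silico_digest",
    "generate_scenario",
    "load_truth",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# non-stop codons per amino acid, sorted for deterministic indexing
_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    _CODONS.setdefault(_aa, []).append(_codon)
_STOPS = sorted(standard_dna_table.stop_codons)


def in_silico_digest(protein: str, min_len: int = 1, max_len: int = 10**9) -> list[str]:
    """Tryptic fragments: cleave after K or R except when followed by P.

    Fragments outside [min_len, max_len] are dropped; before length filtering
    the fragments concatenate back to the input.
    """
    bad = set(protein) - set(AA20)
    if bad:
        raise ValueError(f"invalid residues for digestion: {sorted(bad)}")
    fragments = []
    start = 0
    for i, aa in enumerate(protein):
        if aa in "KR" and (i + 1 == len(protein) or protein[i + 1] != "P"):
            fragments.append(protein[start : i + 1])
            start = i + 1
    if start < len(protein):
        fragments.append(protein[start:])
    return [f for f in fragments if min_len <= len(f) <= max_len]


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic scenario.

    Defaults are a scaled-down mimicry of a real venom-gland experiment:
    ~2,000 expressed body genes, 50 venom genes carrying ~20 sampled tryptic
    peptides each (~1,000 true peptide observations plus a 5% contaminant
    fraction), 1,000 sub-threshold artifact contigs, secretion signals planted
    in 35% of venom vs 5% of body proteins, and 3 of 50 GO terms enriched in
    venom at odds 8.
    """

    seed: int = 0
    n_body_genes: int = 2000
    n_venom_genes: int = 50
    n_artifact_contigs: int = 1000
    transcript_length_distribution: tuple[float, float] = (7.0, 0.45)  # ln bp
    expression_model: tuple[float, float] = (1.0, 1.2)  # ln abundance
    venom_expression_log_boost: float = 1.5
    artifact_tpm_ceiling: float = 0.9
    peptides_per_venom_protein: float = 20.0
    contaminant_peptide_fraction: float = 0.05
    true_peptide_probability_params: tuple[float, float] = (8.0, 2.0)
    noise_peptide_probability_params: tuple[float, float] = (2.0, 8.0)
    signal_rate_venom: float = 0.35
    signal_rate_body: float = 0.05
    n_go_terms: int = 50
    n_enriched_terms: int = 3
    enrichment_odds: float = 8.0
    total_reads: int = 500_000
    shared_block_fraction: float = 0.04  # venom proteins sharing a 25-aa block

    def validate(self) -> None:
        counts = (
            self.n_body_genes, self.n_venom_genes, self.n_artifact_contigs,
            self.n_go_terms, self.n_enriched_terms, self.total_reads,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        props = (
            self.contaminant_peptide_fraction, self.signal_rate_venom,
            self.signal_rate_body, self.shared_block_fraction,
        )
        if any(not 0.0 <= p <= 1.0 for p in props):
            raise ValueError("proportions must lie in [0, 1]")
        for a, b in (self.true_peptide_probability_params,
                     self.noise_peptide_probability_params):
            if a <= 0 or b <= 0:
                raise ValueError("Beta parameters must be > 0")
        if self.peptides_per_venom_protein < 0:
            raise ValueError("peptides_per_venom_protein must be >= 0")
        if self.n_enriched_terms > self.n_go_terms:
            raise ValueError("n_enriched_terms cannot exceed n_go_terms")
        if self.n_venom_genes == 0 and self.contaminant_peptide_fraction > 0:
            raise ValueError(
                "contaminant peptides are defined as a fraction of the true "
                "peptide pool; with zero venom genes no peptides can be produced"
            )


@dataclass
class ScenarioTruth:
    """Planted ground truth for scoring the pipeline."""

    labels: dict[str, str]  # transcript id -> venom | body | artifact
    true_abundance: dict[str, float]
    signal_flags: dict[str, bool]  # per gene transcript
    cleavage_positions: dict[str, int | None]
    gene_terms: dict[str, list[str]]
    enriched_terms: list[str]
    peptide_origin: list[str]  # per peptide-table row: transcript id | contaminant

    def venom_ids(self) -> set[str]:
        return {t for t, lab in self.labels.items() if lab == "venom"}


@dataclass
class Scenario:
    config: ScenarioConfig
    transcripts: list[tuple[str, str]]  # (id, nucleotide sequence)
    proteins: dict[str, str]  # gene transcript id -> planted protein
    counts: pd.DataFrame  # transcript_id, length_bp, count, ambiguity_group
    peptides: pd.DataFrame  # sequence, probability, charge, spectral_count
    go_map: dict[str, list[str]]
    truth: ScenarioTruth


def _random_protein(rng: np.random.Generator, n_aa: int) -> str:
    return "".join(AA20[i] for i in rng.integers(0, 20, size=n_aa))


def _plant_signal(rng: np.random.Generator, protein: str) -> tuple[str, int]:
    """Overwrite the N-terminus with a detectable tripartite signal peptide.

    Layout (1-based): M, one K/R, twelve hydrophobic residues, then A-x-A so
    the first qualifying cleavage position is exactly residue 17 (no earlier
    position can qualify because the h-region and x avoid small residues).
    """
    hydrophobic = "LIVF"
    nonsmall = "DEFHIKLMNPQRVWY"
    sig = (
        "M"
        + "KR"[rng.integers(0, 2)]
        + "".join(hydrophobic[i] for i in rng.integers(0, 4, size=12))
        + "A"
        + nonsmall[rng.integers(0, len(nonsmall))]
        + "A"
    )
    return sig + protein[len(sig):], 17


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    parts = []
    for aa in protein:
        codons = _CODONS[aa]
        parts.append(codons[rng.integers(0, len(codons))])
    parts.append(_STOPS[rng.integers(0, len(_STOPS))])
    return "".join(parts)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _gene(
    rng: np.random.Generator, cfg: ScenarioConfig, plant_signal: bool
) -> tuple[str, str, int | None]:
    """One gene transcript: 5'UTR (with in-frame stop guard), CDS, 3'UTR.

    Returns (transcript, protein, cleavage position or None).  The guard stop
    immediately upstream of the start codon makes the coding-frame stop-free
    run begin exactly at the initiator methionine, mimicking the common
    upstream in-frame stop of real 5'UTRs.
    """
    mu, sd = cfg.transcript_length_distribution
    total = int(rng.lognormal(mu, sd))
    utr5 = int(rng.integers(12, 61))
    utr3 = int(rng.integers(12, 61))
    n_aa = max(60, (total - utr5 - utr3) // 3 - 1)
    protein = "M" + _random_protein(rng, n_aa - 1)
    cleavage: int | None = None
    if plant_signal:
        protein, cleavage = _plant_signal(rng, protein)
    seq = (
        _random_nt(rng, utr5 - 3)
        + "TAA"
        + _reverse_translate(rng, protein)
        + _random_nt(rng, utr3)
    )
    return seq, protein, cleavage


def generate_scenario(
    config: ScenarioConfig | None = None, out_dir: str | Path | None = None
) -> Scenario:
    """Generate one scenario; optionally write its files under out_dir.

    Files written: transcripts.fasta, counts.tsv, peptides.tsv, go_map.tsv,
    truth.json.
    """
    cfg = config or ScenarioConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    labels: dict[str, str] = {}
    proteins: dict[str, str] = {}
    signal_flags: dict[str, bool] = {}
    cleavages: dict[str, int | None] = {}
    transcripts: list[tuple[str, str]] = []

    gene_plan = [("VEN", cfg.n_venom_genes, cfg.signal_rate_venom),
                 ("BOD", cfg.n_body_genes, cfg.signal_rate_body)]
    for prefix, n, rate in gene_plan:
        for i in range(n):
            tid = f"{prefix}{i+1:05d}"
            plant = bool(rng.random() < rate)
            seq, protein, cleavage = _gene(rng, cfg, plant)
            transcripts.append((tid, seq))
            proteins[tid] = protein
            labels[tid] = "venom" if prefix == "VEN" else "body"
            signal_flags[tid] = plant
            cleavages[tid] = cleavage

    # a few venom proteins share a 25-aa block (shared/razor peptides)
    venom_ids = [t for t, lab in labels.items() if lab == "venom"]
    n_shared = int(round(cfg.shared_block_fraction * len(venom_ids)))
    if n_shared and len(venom_ids) >= 2:
        for k in range(n_shared):
            dst, src = rng.choice(len(venom_ids), size=2, replace=False)
            dst_id, src_id = venom_ids[dst], venom_ids[src]
            block = proteins[src_id][25:50]
            p = proteins[dst_id]
            if len(block) == 25 and len(p) >= 50:
                proteins[dst_id] = p[:25] + block + p[50:]
                # regenerate the transcript so CDS and protein stay consistent
                tid_index = next(
                    i for i, (t, _) in enumerate(transcripts) if t == dst_id
                )
                utr5 = int(rng.integers(12, 61))
                utr3 = int(rng.integers(12, 61))
                seq = (
                    _random_nt(rng, utr5 - 3)
                    + "TAA"
                    + _reverse_translate(rng, proteins[dst_id])
                    + _random_nt(rng, utr3)
                )
                transcripts[tid_index] = (dst_id, seq)

    mu_l, sd_l = cfg.transcript_length_distribution
    for i in range(cfg.n_artifact_contigs):
        tid = f"ART{i+1:05d}"
        L = max(150, int(rng.lognormal(mu_l - 0.7, sd_l)))
        transcripts.append((tid, _random_nt(rng, L)))
        labels[tid] = "artifact"

    # expression and read counts
    mu_e, sd_e = cfg.expression_model
    theta: dict[str, float] = {}
    for tid, lab in labels.items():
        if lab == "artifact":
            theta[tid] = 0.0
        elif lab == "venom":
            theta[tid] = float(rng.lognormal(mu_e + cfg.venom_expression_log_boost, sd_e))
        else:
            theta[tid] = float(rng.lognormal(mu_e, sd_e))
    lengths = {tid: len(seq) for tid, seq in transcripts}
    weights = np.array([theta[t] * lengths[t] for t, _ in transcripts])
    wsum = weights.sum()
    counts_arr = np.zeros(len(transcripts))
    if wsum > 0:
        counts_arr = rng.poisson(cfg.total_reads * weights / wsum).astype(float)
    # artifacts: fractional counts targeting a TPM strictly below the ceiling
    gene_rate_sum = sum(
        c / lengths[t]
        for (t, _), c in zip(transcripts, counts_arr)
        if labels[t] != "artifact"
    )
    for i, (tid, _) in enumerate(transcripts):
        if labels[tid] == "artifact" and gene_rate_sum > 0:
            target_tpm = float(rng.uniform(0.05, 0.9)) * cfg.artifact_tpm_ceiling
            counts_arr[i] = target_tpm * gene_rate_sum * lengths[tid] / 1e6

    counts = pd.DataFrame(
        {
            "transcript_id": [t for t, _ in transcripts],
            "length_bp": [lengths[t] for t, _ in transcripts],
            "count": counts_arr,
            "ambiguity_group": ["" for _ in transcripts],
        }
    )

    # peptide observations
    rows = []
    origins: list[str] = []
    alpha_t, beta_t = cfg.true_peptide_probability_params
    alpha_n, beta_n = cfg.noise_peptide_probability_params
    charges, charge_p = np.array([1, 2, 3]), np.array([0.05, 0.60, 0.35])
    for tid in venom_ids:
        pool = in_silico_digest(proteins[tid], 5, 45)
        if not pool:
            continue
        n_obs = int(rng.poisson(cfg.peptides_per_venom_protein))
        for _ in range(n_obs):
            seq = pool[rng.integers(0, len(pool))]
            rows.append(
                (
                    seq,
                    float(rng.beta(alpha_t, beta_t)),
                    int(rng.choice(charges, p=charge_p)),
                    int(1 + rng.poisson(1.0)),
                )
            )
            origins.append(tid)
    n_true = len(rows)
    f = cfg.contaminant_peptide_fraction
    n_contam = int(rng.poisson(n_true * f / (1.0 - f))) if (f > 0 and n_true) else 0
    for _ in range(n_contam):
        L = int(rng.integers(6, 21))
        seq = _random_protein(rng, L - 1) + "KR"[rng.integers(0, 2)]
        rows.append(
            (
                seq,
                float(rng.beta(alpha_n, beta_n)),
                int(rng.choice(charges, p=charge_p)),
                int(1 + rng.poisson(1.0)),
            )
        )
        origins.append("contaminant")
    if rows:
        perm = rng.permutation(len(rows))
        rows = [rows[i] for i in perm]
        origins = [origins[i] for i in perm]
    peptides = pd.DataFrame(
        rows, columns=["sequence", "probability", "charge", "spectral_count"]
    )

    # GO annotations with planted venom-enriched terms.  Background carriage
    # is Bernoulli per gene; the enriched terms are planted in an exact-count
    # subset of venom genes at the configured odds ratio, so the planted
    # structure is guaranteed, not merely expected.
    terms = [f"GO:{i+1:07d}" for i in range(cfg.n_go_terms)]
    enriched_set = set(terms[: cfg.n_enriched_terms])
    base_q = rng.uniform(0.03, 0.08, size=cfg.n_go_terms)
    go_map: dict[str, list[str]] = {}
    odds = cfg.enrichment_odds
    for tid, lab in labels.items():
        if lab == "artifact":
            continue
        carried = []
        for t_idx, term in enumerate(terms):
            if lab == "venom" and term in enriched_set:
                continue  # planted below with exact counts
            if rng.random() < base_q[t_idx]:
                carried.append(term)
        go_map[tid] = carried
    for t_idx, term in enumerate(terms):
        if term not in enriched_set or not venom_ids:
            continue
        q = base_q[t_idx]
        p_venom = odds * q / (1.0 + (odds - 1.0) * q)
        n_carry = int(round(p_venom * len(venom_ids)))
        for j in rng.choice(len(venom_ids), size=n_carry, replace=False):
            go_map[venom_ids[j]].append(term)
    enriched = sorted(enriched_set)

    truth = ScenarioTruth(
        labels=labels,
        true_abundance=theta,
        signal_flags=signal_flags,
        cleavage_positions=cleavages,
        gene_terms=go_map,
        enriched_terms=enriched,
        peptide_origin=origins,
    )
    scenario = Scenario(
        config=cfg,
        transcripts=transcripts,
        proteins=proteins,
        counts=counts,
        peptides=peptides,
        go_map=go_map,
        truth=truth,
    )
    if out_dir is not None:
        write_scenario(scenario, out_dir)
    return scenario


def write_scenario(scenario: Scenario, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "transcripts.fasta",
        "counts": out / "counts.tsv",
        "peptides": out / "peptides.tsv",
        "go_map": out / "go_map.tsv",
        "truth": out / "truth.json",
    }
    with open(paths["fasta"], "w") as fh:
        for tid, seq in scenario.transcripts:
            fh.write(f">{tid}\n{seq}\n")
    scenario.counts.to_csv(paths["counts"], sep="\t", index=False, float_format="%.6f")
    scenario.peptides.to_csv(
        paths["peptides"], sep="\t", index=False, float_format="%.6f"
    )
    with open(paths["go_map"], "w") as fh:
        for gene in sorted(scenario.go_map):
            fh.write(f"{gene}\t{';'.join(scenario.go_map[gene])}\n")
    truth = scenario.truth
    payload = {
        "labels": truth.labels,
        "true_abundance": truth.true_abundance,
        "signal_flags": truth.signal_flags,
        "cleavage_positions": truth.cleavage_positions,
        "gene_terms": truth.gene_terms,
        "enriched_terms": truth.enriched_terms,
        "peptide_origin": truth.peptide_origin,
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return paths


def load_truth(path: str | Path) -> ScenarioTruth:
    """Read a truth.json written by write_scenario."""
    with open(path) as fh:
        payload = json.load(fh)
    return ScenarioTruth(**payload)
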