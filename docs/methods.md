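# Methods

`venomics` implements an integrative transcriptome–proteome procedure for
identifying the secreted venom proteins of an organism without a reference
genome, together with the validation statistics that support such an
identification and a ground-truthed synthetic data generator that makes every
stage testable at desk scale.

## The identification model

The procedure rests on two observations. First, a de novo transcriptome
assembly of the tissue producing the secretion contains the coding sequence of
every venom protein, buried among thousands of ordinary ("body") transcripts
and a large tail of low-quality artifact contigs. Second, peptides sequenced
by LC-MS/MS from the purified secretion derive almost exclusively from the
venom proteins, so mapping them back into the translated transcriptome picks
the venom transcripts out of the background.

The stages, in order:

1. **Expression filter.** Expression of every contig is estimated in
   transcripts per million, TPM_i = (c_i/l_i) / Σ_j (c_j/l_j) × 10⁶, from a
   read-count table; counts belonging to an ambiguity group are split across
   the group's members proportionally to current abundance estimates and
   iterated to a fixed point (EM; relative tolerance 10⁻⁸, at most 200
   iterations), which reduces to the closed-form rate formula when every count
   is unique. Contigs with TPM ≥ 1 are kept; the threshold is inclusive so the
   stated value itself survives. Assembly quality before and after is
   summarised by the transcript count (> 100 bp), N50 (descending
   cumulative-sum definition: the length reaching half the total assembled
   bases) and mean length.
2. **Search database.** Every retained contig is translated in all six
   reading frames under the standard genetic code (codons containing N
   translate to X; stops to `*`). Search ORFs are maximal stop-free runs of at
   least 5 aa — stop-to-stop, with no start-codon requirement, because
   peptides can fall anywhere in a coding region and a tryptic peptide cannot
   span a stop. Frame +1 starts at offset 0 of the forward strand, −1 at
   offset 0 of the reverse complement; ORF coordinates are 0-based half-open
   within the frame translation.
3. **Peptide filter cascade.** Identified peptides are kept when length > 4
   residues, probability > 0.5 (strict inequalities) and charge ≠ +1.
4. **Mapping.** Exact substring search of each filtered peptide against every
   search ORF, with isoleucine and leucine collapsed to one symbol (they are
   isobaric and indistinguishable by the instrument; a flag disables this).
   All placements are reported; a peptide is *unique* when its placements fall
   in a single transcript.
5. **Protein inference.** Shared peptides are razor-assigned to the single
   candidate transcript with the highest current distinct-peptide count
   (ties: higher current spectral count, then lexicographically smallest id),
   so every retained peptide is credited exactly once. A transcript becomes a
   venom-protein identification when it retains ≥ 2 distinct peptide
   sequences *and* its protein probability 1 − Π(1 − p_i) over those peptides
   exceeds 0.7. The probability aggregation treats the distinct peptides as
   independent evidence; when a sequence is observed several times, the best
   observation's probability enters the product (the repeat observations
   instead accumulate into the spectral count, keeping the two evidence axes
   separate). Each identification reports its representative ORF (the one
   holding the most retained placements, ties to the longer), coverage (union
   of matched intervals over ORF length) and normalised spectral abundance
   (SpC/ORF-length, normalised to sum to 1 over identifications).
6. **Validation.** (a) Secretion signals are called on each protein's
   N-terminal sequence by a transparent heuristic over the classical
   tripartite signal-peptide architecture: a K/R among residues 1–5, an
   8-residue window within residues 6–25 with mean Kyte–Doolittle hydropathy
   ≥ 1.5, and a cleavage position in residues 15–35 whose −3 and −1 residues
   are small (A/G/S/C/T); sequences under 15 aa are never called. The signal
   rates of identified venom proteins and the remaining expressed proteins
   (optionally the full expressed set) are compared by a 2×2 Pearson
   chi-square without continuity correction. The heuristic deliberately trades
   the accuracy of a trained predictor for auditability; externally computed
   predictions can be imported from TSV and substituted. (b) Best-hit E-value
   distributions of two transcript subsets against a common database are
   binned at descending powers of ten (defaults 10⁻¹⁰⁰, 10⁻⁵⁰, 10⁻²⁰, 10⁻¹⁰,
   10⁻⁵, 10⁻², 1; a value on an edge falls in the more significant bin) and
   compared by a chi-square homogeneity test after collapsing jointly empty
   bins. (c) Conserved-domain sets are compared as 7-region Venn counts.
7. **Enrichment.** GO terms of the identification set are tested against the
   expressed population with the one-sided hypergeometric upper tail
   P(X ≥ k), X ~ Hypergeom(N, K, n), Bonferroni-corrected by the number of
   terms with K ≥ 1. The GO hierarchy is not propagated: annotations are a
   flat gene → term map, or the composition of a gene → protein-family table
   with a family → term translation.
8. **Extrapolation.** An independently validated true-positive rate v/t
   (e.g. RT-PCR confirmation of a random subset) scales an identification
   count to an estimate of genuine venom genes: ⌊identified × v/t⌋.

Percentages in reports are rounded half away from zero to integers and always
accompanied by their numerator/denominator pair.

## The synthetic-data generator

`generate_scenario` emulates the statistical structure of the experiment, not
its physics. Defaults: 2,000 body genes, 50 venom genes, 1,000 artifact
contigs; transcript lengths lognormal(ln-mean 7.0, ln-sd 0.45) bp (median
≈ 1.1 kb); true abundance lognormal(1.0, 1.2) with a +1.5 natural-log boost
for venom genes (venom transcripts are strongly expressed in the source
tissue, and the boost keeps every real gene above the 1-TPM filter at the
simulated depth of 500k reads); artifact contigs receive fractional counts
drawn to land strictly below a 0.9-TPM ceiling. Each gene is a 5′UTR ending
in an in-frame stop, a CDS reverse-translated from a random protein (≥ 60 aa),
and a 3′UTR; the guard stop makes the coding-frame ORF begin exactly at the
initiator methionine, as upstream in-frame stops commonly do in real 5′UTRs.
Planted secretion signals (rate 0.35 venom, 0.05 body) are a 17-residue
M–[KR]–12×[LIVF]–A–x–A prefix whose first qualifying cleavage position is
exactly residue 17. About 4% of venom proteins share a 25-aa block with
another venom protein to exercise razor assignment.

Peptides are in-silico tryptic fragments (cleave after K/R, not before P;
5–45 aa) sampled with replacement, Poisson(20) observations per venom
protein; observation probabilities are Beta(8, 2) for true peptides and
Beta(2, 8) for the contaminant fraction (5% of the pool, random tryptic-like
sequences), so most true peptides survive the > 0.5 filter and most
contaminants do not. Charges are drawn {+1: 0.05, +2: 0.60, +3: 0.35};
spectral counts are 1 + Poisson(1).

GO annotations use 50 terms with background carriage Bernoulli(q),
q ~ U(0.03, 0.08) per term. The three enriched terms are planted in an
exact-count random subset of venom genes of size round(p·50), with
p = 8q/(1 + 7q) the carrier probability at odds ratio 8: planting by exact
counts makes the enriched structure a guarantee of the generator rather than
a binomial expectation, which is what "planted ground truth" has to mean for
recovery to be a sharp criterion.

All draws come from one `numpy` generator seeded once per scenario in a fixed
order, so outputs are byte-identical under a repeated seed.

**What the generator does not emulate** — and therefore what passing tests do
not show about real data: raw reads, spectra and their noise models; realistic
amino-acid composition and homology structure (proteins are i.i.d. over the
20-letter alphabet, so peptide mapping is nearly collision-free and coverage
runs higher than a real experiment's ≈ 23%); post-translational
modifications; genuinely ambiguous multi-mapping read structure (the EM path
is exercised by dedicated unit tests instead); and a trained signal-peptide
model (the planted motif is, by construction, detectable by the built-in
heuristic).

## Numerical and design notes

- EM convergence is measured as the maximum relative change in per-transcript
  counts; with no ambiguity groups the closed form is returned after one
  sweep. All-zero counts short-circuit to all-zero TPM.
- N50 of an empty set is 0; ties at the half-total boundary resolve to the
  length that reaches the boundary.
- `longest_orf` breaks ties by frame order +1, +2, +3, −1, −2, −3, then by
  smallest start coordinate.
- The chi-square helpers signal degenerate inputs (a zero column marginal;
  fewer than two jointly nonempty bins) as errors rather than returning NaN.
- Scenario sizes were chosen so a full pipeline run takes a few seconds and
  the ten-seed recovery suite about a minute on one core, while preserving
  the class imbalance (venom ≪ body ≪ total contigs) that makes the
  identification problem nontrivial.

## Known limitations

- The razor assignment is greedy and order-deterministic, not a global
  optimum; pathological tie structures could assign differently than a
  parsimony solver would.
- The signal heuristic's false-positive rate on random-composition proteins
  is a few percent, so the reported body-signal fraction sits above the
  planted rate; the venom/body contrast remains the tested quantity.
- Protein probability assumes independent peptide evidence; correlated
  misidentifications (e.g. shared modified forms) would inflate it.
- No FDR control beyond the probability thresholds; target-decoy search is
  out of scope because the pipeline starts from an already-scored peptide
  list.
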