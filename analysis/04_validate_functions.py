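#!/usr/bin/env python
"""Validate the identified venom set: secretion-signal enrichment and GO
over-representation.

Reads the pipeline report produced by 03 and re-states its two validation
statistics: the 2x2 chi-square comparing heuristic secretion-signal calls in
identified venom proteins against the remaining expressed proteins, and the
Bonferroni-corrected hypergeometric enrichment of GO terms, checked against the
planted enriched terms.
"""

import json
from pathlib import Path

import pandas as pd

OUT = Path("results")

report = json.loads((OUT / "report.json").read_text())

sig = report["signals"]
chi = sig["chi_square"]
print(
    f"secretion signals: venom {sig['venom']['num']}/{sig['venom']['den']} "
    f"({sig['venom']['pct']}%) vs body {sig['comparison']['num']}/"
    f"{sig['comparison']['den']} ({sig['comparison']['pct']}%)"
)
print(
    f"chi-square = {chi['statistic']:.1f} (df {chi['df']}), "
    f"p = {chi['p_value']:.3g}"
    + (" -> below the 1e-4 bound" if chi["p_value"] < 1e-4 else "")
)

enr = report["enrichment"]
enrichment = pd.read_csv(OUT / "enrichment.tsv", sep="\t")
sig_terms = enrichment[enrichment["significant"]]
print(
    f"\nGO enrichment: {len(sig_terms)}/{enr['n_terms_tested']} terms "
    f"significant at Bonferroni alpha = {enr['alpha']}"
)
print(
    sig_terms[["term_id", "study_count", "population_count", "p_raw", "p_bonferroni"]]
    .to_string(index=False)
)
planted = set(report["truth"]["planted_enriched_terms"])
recovered = set(report["truth"]["recovered_enriched_terms"])
print(f"planted enriched terms recovered: {len(recovered)}/{len(planted)}")
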