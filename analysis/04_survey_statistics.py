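#!/usr/bin/env python
"""Recompute the survey's published statistics from the packaged fixtures.

Expands the reconstructed count tables into pseudo-rosters, runs them through
the same statistics code used for pipeline output, and writes
results/survey_statistics.tsv. Every figure printed here is recomputed, not
transcribed.
"""

from pathlib import Path

from mycoscreen import data as fixtures
from mycoscreen.io import write_tsv
from mycoscreen.stats import (coinfection_summary, fisher_exact,
                              method_agreement, prevalence_table)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    overall = prevalence_table(fixtures.total_roster(), "phylum")[-1]
    rows.append(("overall_prevalence_pct", overall.pct,
                 f"{overall.positives}/{overall.n} hosts virus-positive"))
    for rank in ("phylum", "subphylum", "order"):
        for r in prevalence_table(fixtures.table1_roster(rank), rank):
            if r.taxon != "Total":
                rows.append((f"{rank}:{r.taxon}", r.pct,
                             f"{r.positives}/{r.n}"))
    morph = fixtures.morphology_roster()
    for name in ("polycentric", "monocentric"):
        grp = [h for h in morph if h.morphology == name]
        r = prevalence_table(grp, "phylum")[-1]
        rows.append((f"morphology:{name}_pct", r.pct, f"{r.positives}/{r.n}"))
    table = fixtures.morphology_table()
    p = fisher_exact(table)
    rows.append(("morphology_fisher_p", p,
                 f"2x2 table [[{table.a},{table.b}],[{table.c},{table.d}]]"))
    agreement = fixtures.agreement_roster()
    rows.append(("method_agreement_pct", method_agreement(agreement),
                 f"{len(agreement)} isolates screened by both methods"))
    counts = fixtures.coinfection_counts()
    mean, median = coinfection_summary(counts)
    rows.append(("mean_viruses_per_host", mean,
                 f"{sum(counts)} viruses over {len(counts)} hosts"))
    rows.append(("median_viruses_per_host", median, "midpoint of counts"))

    ROOT.mkdir(exist_ok=True)
    out = ROOT / "survey_statistics.tsv"
    write_tsv(out, ["statistic", "value", "detail"], rows)
    print(f"wrote {len(rows)} statistics to {out}")
    for name, value, detail in rows[:1] + rows[-6:]:
        print(f"  {name} = {value}  ({detail})")
    print(f"zoosporic morphology association: Fisher exact p = {p:.2e}")


if __name__ == "__main__":
    main()
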