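#!/usr/bin/env python
"""Screen the simulated transcriptomes and reduce them to unique viruses.

Runs the full pipeline (ORFs -> profile scan -> panel confirmation with
mito-code retranslation -> endogeny check -> census -> statistics) over
results/bundle/ and writes the report TSVs to results/reports/, then checks
the outcome against the planted truth.
"""

from pathlib import Path

from mycoscreen.config import Config
from mycoscreen.pipeline import run_pipeline
from mycoscreen.simulate import (expected_positive,
                                 expected_unique_virus_count, read_truth)

ROOT = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    bundle = SCRATCH / "bundle"
    if not bundle.exists():
        raise SystemExit("run 01_simulate_survey.py first")
    res = run_pipeline(Config(), bundle / "roster.tsv",
                       bundle / "contigs.fasta", bundle / "panel",
                       bundle / "genomes.fasta", out_dir=ROOT / "reports")
    truths = {t.host_id: t for t in read_truth(bundle / "truth.tsv")}
    n_conf = sum(1 for c in res.calls if c.confirmed)
    uniq = sum(e.n_viruses for e in res.census.values())
    pos = sum(1 for v in res.screen.values() if v == "positive")
    print(f"{len(res.contig_results)} contigs screened; "
          f"{n_conf} confirmed viral; {pos} positive hosts; "
          f"{uniq} unique viruses after the conservative census")
    screen_ok = sum(res.screen[h] == ("positive" if expected_positive(t)
                                      else "negative")
                    for h, t in truths.items())
    census_ok = sum(res.census[h].n_viruses == expected_unique_virus_count(t)
                    for h, t in truths.items())
    print(f"truth check: {screen_ok}/{len(truths)} isolate calls and "
          f"{census_ok}/{len(truths)} census counts match the planted truth")
    print(f"reports in {ROOT / 'reports'}")


if __name__ == "__main__":
    main()
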