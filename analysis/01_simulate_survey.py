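#!/usr/bin/env python
"""Generate the truth-annotated synthetic survey used by the later steps.

Writes a 60-host bundle (roster, panel, transcriptomes with planted viral
contigs, genomes with endogenized copies, truth table) to scratch/bundle/.
"""

from pathlib import Path

from mycoscreen.simulate import SurveyParams, gen_survey, write_bundle

SEED = 42
# bulky FASTA/FASTQ output lives under scratch/; small tables under results/
OUT = Path(__file__).resolve().parent.parent / "scratch" / "bundle"


def main() -> None:
    params = SurveyParams(n_hosts=60)
    bundle = gen_survey(params, seed=SEED)
    paths = write_bundle(bundle, OUT)
    plants = [p for t in bundle.truths for p in t.planted]
    infected = sum(1 for t in bundle.truths if t.planted)
    print(f"survey of {params.n_hosts} hosts written to {OUT}")
    print(f"  contigs: {len(bundle.contigs)}  planted viruses: {len(plants)}"
          f"  infected hosts: {infected}")
    print(f"  endogenized: {sum(p.is_endogenous for p in plants)}"
          f"  mitovirus: {sum(p.uses_mito_code for p in plants)}"
          f"  fragments: {sum(p.completeness != 'complete' for p in plants)}")
    for name, path in paths.items():
        print(f"  {name}: {path.relative_to(OUT.parent.parent)}")


if __name__ == "__main__":
    main()
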