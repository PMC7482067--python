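# mycoscreen

A desk-scale, fully tested re-creation of an *in silico* mycovirus survey
pipeline: detect RNA-dependent RNA polymerase (RdRp)–bearing contigs in
fungal transcriptome assemblies, classify them into the five Riboviria
branches, separate exogenous infections from endogenized virus-like
elements, extend contigs from reads, reduce per-host contig lists to unique
viruses with conservative criteria, and compute survey-level prevalence,
coinfection, and association statistics.

The package is aimed at mycologists and viromics researchers who want the
*screening and census logic* of a transcriptome-mining virus survey as an
auditable, reusable library — with a synthetic-data generator standing in
for raw sequencing archives, so every stage can be verified against planted
truth.

## The method

RdRp is the only gene conserved across RNA viruses, so its presence in a
transcript is diagnostic of infection. The pipeline chains:

1. **ORF prediction** — six-frame, stop-to-stop ORFs ≥ 100 aa, translated
   under the standard code (or the mold-mitochondrial code, table 4, where
   TGA = Trp — required for mitoviruses, whose ORFs are interrupted by
   internal TGA stops under the standard code).
2. **Profile scan** — each ORF is locally aligned (Smith–Waterman with
   affine gaps) against position-specific log-odds profiles built from
   aligned RdRp families, `score(col, aa) = log2(((n_aa + τ·b_aa)/(n_col +
   τ))/b_aa)` in bits. The fraction of profile columns spanned by the best
   hit is the **domain coverage** used by the census, and the span's
   position classifies hits as complete / N-terminal / C-terminal fragments.
3. **Reference confirmation** — profile hits are aligned against a labelled
   protein panel (BLOSUM62, gaps 11/1) and accepted only if the best
   reference is viral with Karlin–Altschul expectation
   `E = K·m·n·e^{−λS} < 10⁻¹⁰`. The best hit assigns the Riboviria branch
   (1–5); a mitovirus best-hit triggers mito-code retranslation.
4. **Endogeny screen** — confirmed contigs are matched against the host's
   genome (k-mer–seeded local nucleotide alignment). A strong match
   (≥ 90 % identity over ≥ 200 nt) marks the contig endogenous (or *likely*
   endogenous when only a relative's genome exists); endogenized elements
   are excluded from the exogenous census.
5. **Extension** — iterative seed-based extension: reads overlapping a
   contig end by ≥ 30 nt at ≥ 80 % identity (and ≥ 90 % identical to the
   original seed where they overlap it) vote base-by-base on the overhang;
   ≥ 2 concordant reads append a base; blocks of 10 cycles run until a
   block leaves the contig unchanged.
6. **Census** — per host and branch: a single contig is one virus; exactly
   one N- plus one C-terminal fragment concatenate into one virus;
   otherwise every contig with > 60 % domain coverage counts, and if none
   qualifies only the highest-coverage contig is kept.
7. **Statistics** — prevalence by phylum/subphylum/order (positive = either
   screening method positive), two-sided Fisher exact test (minimum-
   likelihood convention) for the polycentric-vs-monocentric association,
   coinfection mean/median, paired-method concordance, and TPM as a titer
   proxy.

## Worked example

```
$ python analysis/01_simulate_survey.py
survey of 60 hosts written to .../scratch/bundle
  contigs: 767  planted viruses: 47  infected hosts: 22
  endogenized: 3  mitovirus: 7  fragments: 15

$ python analysis/02_screen_and_census.py
767 contigs screened; 47 confirmed viral; 22 positive hosts; 41 unique
viruses after the conservative census
truth check: 22/22 isolate calls and 22/22 census counts match the planted
truth
```

The 47 planted contigs reduce to 41 unique viruses because fragment pairs
concatenate and sub-threshold-coverage contigs collapse onto their branch's
best representative; every isolate-level call and per-host census count
equals the planted truth in the error-free setting. The same bundle can be
driven through the CLI (`mycoscreen simulate | all | extend | stats`), and
`analysis/04_survey_statistics.py` recomputes the survey-scale figures,
e.g.:

```
overall_prevalence_pct = 21.6  (72/333 hosts virus-positive)
morphology_fisher_p = 3.35e-05  (2x2 table [[12,14],[11,109]])
mean_viruses_per_host = 2.4  (85 viruses over 36 hosts)
```

## Layout

- `src/mycoscreen/` — the library: `simulate` (synthetic surveys), `orfs`,
  `pssm`, `classify`, `endogeny`, `extension`, `census`, `stats`,
  `pipeline` (orchestration), `cli`, `io`/`roster`/`panel`/`config`
  (formats), `data` (packaged count fixtures).
- `analysis/` — numbered drivers for the narrative: simulate → screen →
  extend → statistics; tables land in `results/`, bulky FASTA in
  `scratch/`.
- `tests/` — unit, property (hypothesis), oracle-agreement, and end-to-end
  acceptance tests.
- `docs/methods.md` — model assumptions, parameter choices, and what the
  synthetic data does and does not emulate.
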