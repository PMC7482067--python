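# Methods

## Scope and design

`mycoscreen` re-creates the computational core of a transcriptome-mining
mycovirus survey at desk scale. The wet-lab stages (dsRNA chromatography,
library preparation, de novo assembly, phylogenetic tree inference) are out
of scope; their outcomes appear only as roster fields (the in vitro
screening column) or as inputs (assembled contigs). All coordinates are
0-based half-open internally; human-readable reports are 1-based inclusive.

## Profile model

Detection uses position-specific scoring matrices (PSSMs) with affine gap
penalties rather than full profile HMMs. The census consumes only a score
and a column span, which a PSSM provides while remaining fully testable
against an exhaustive alignment-path oracle. Match columns are alignment
columns with gap fraction ≤ 0.5 (exactly 0.5 is kept); per-column scores are

    score(col, aa) = log2( ((n_aa + τ · b_aa) / (n_col + τ)) / b_aa )

with pseudocount mass τ = 1 distributed by the Robinson–Robinson background
frequencies (the BLOSUM62 background). Scanning is Smith–Waterman over the
profile columns with gap-open 4 bits and gap-extend 1 bit; hits below
20 bits are discarded. These three values are this package's own defaults —
the scan stage needs *some* significance gate, and the downstream E-value
gate (below) is the decisive filter, so the bit gate only has to reject
random ORFs, which it does with a wide margin at 20 bits. A hit is
"complete" on a side when its span reaches within 5 % of that profile end;
complete on both sides → `complete`, on the start side only → `n_term`
(the fragment holds the domain's N terminus), on the end side only →
`c_term`, neither → `internal`. Domain coverage is measured against the
profile's match-column count; hit coverage feeds the census unmodified.

## Reference confirmation and E-values

A labelled protein panel replaces the public databases: each reference
carries a Riboviria branch (1–5 or unassigned), an `is_viral` flag (the
stand-in for a taxonomy lookup), and an `is_mitovirus` flag. ORFs with a
profile hit are aligned to every reference with Smith–Waterman under
BLOSUM62, gap costs `open + extend·L` with open 11, extend 1; unknown
residues score 0 against everything. Significance uses the Karlin–Altschul
form `E = K·m·n·exp(−λS)` with the literature gapped-BLOSUM62 parameters
λ = 0.267, K = 0.041, `m` the ORF length and `n` the summed panel length.
A hit is confirmed only when the best reference is viral and E < 10⁻¹⁰.
Profile-positive ORFs whose best panel hit misses the gate are reported as
unconfirmed candidates (branch `unassigned`) and enter the census only with
an explicit flag — the default census counts confirmed hits, and whether a
survey should count unconfirmed candidates as positives is left to the
caller because both conventions are defensible.

Best-hit ties are broken by reference id (lexicographic), making
classification invariant to panel order.

## Mitovirus handling

Mitoviruses replicate in mitochondria and their RdRp ORF is intact only
under a code where TGA encodes tryptophan. The pipeline first reads every
contig under the standard code; when the best confirmed reference for a
contig is flagged `is_mitovirus`, the contig is retranslated under the
mold-mitochondrial code (NCBI table 4) and rescanned, and the retranslated
result replaces the standard-code one when it scores at least as well. The
trigger must come from the classifier because a TGA-interrupted ORF still
yields strong partial profile and reference hits — the standard-code
reading merely cannot recover the complete domain (in the synthetic data
its fragments sit below the 60 % census coverage threshold by
construction). Table 4 is the default because fungal mitochondria use the
mold variant; the vertebrate-mitochondrial table differs additionally at
AGA/AGG, and the code id is a parameter rather than a hard-wired choice.

## Endogeny

A transcript matching the host's own DNA genome at high nucleotide identity
is an endogenized virus-like element: transcribed, but not an exogenous
infection. Matching is k-mer–seeded (k = 11) on both strands; seed
diagonals define merged genome windows inside which a local alignment
(match +1, mismatch −1, gap −2 per base) finds the best match, ranked by
aligned length × identity. The call is `endogenous` when identity ≥ 0.90
over ≥ 200 aligned columns against the host's own genome, and only
`likely_endogenous` against a relative's genome — a relative's genome
cannot prove integration in the host itself. Hosts with no genome yield
`unknown`, which the census treats as exogenous (the genome check in the
original protocol ran only where a genome existed). The 0.90 / 200 nt
thresholds are this package's choice — the protocol's BLAST cutoffs are
unstated — and both are configurable. Endogenous and likely-endogenous
calls are excluded from the exogenous census and prevalence and reported
separately.

## Extension

Extension re-creates the seed-based iterative protocol with the published
parameters: a read must overlap a contig end by ≥ 30 nt at ≥ 80 % identity,
and its within-contig portion must stay ≥ 90 % identical to the *original
seed* over the region where they overlap. The three published parameters
leave the exact mapping of identities to read spans open; this
interpretation (edge identity on the read-to-contig overlap, seed identity
on the read-to-original-seed overlap) is the package's documented choice
and both thresholds are configurable. Matching is ungapped — simulated
reads carry substitutions only. Each qualifying read votes base-by-base on
the overhang beyond the contig end; a position is appended only with ≥ 2
supporting reads and a strict majority (a tie truncates the overhang
there). The two-read floor suppresses single-read error propagation in a
consensus step the protocol does not specify. Cycles run in blocks of 10;
a block that leaves the contig unchanged ends the run as `complete`,
otherwise the updated contig seeds the next block, up to 10 blocks. Voting
is deterministic given read order and configuration. A corollary of the
support floor: template positions covered by fewer than two reads (e.g.
the outermost bases under random read placement) are never appended, so
"full" recovery requires ≥ 2× coverage at the extremes.

## Census

Per host, confirmed exogenous calls are grouped by branch:

* singleton group → one virus;
* exactly two contigs, one `n_term` and one `c_term` → one concatenated
  virus (its representative coverage is the capped sum of the two
  fragments' coverages, since calls carry coverage fractions, not column
  spans);
* otherwise each contig with coverage > 0.60 is its own virus; if none
  passes, the single highest-coverage contig is kept (ties: longer contig,
  then lexicographically smaller id).

Coverage exactly 0.60 does **not** pass — the rule is stated with strict
inequalities and is read literally. Concatenation applies only to
the exactly-two-fragments case; with three or more fragments the coverage
rule governs, because the protocol describes only two-contig assemblies.
An isolate is positive when it has at least one confirmed, non-endogenous
call. Deduplication is within-host only; no cross-host sequence clustering
is attempted.

## Statistics

Prevalence tables count an isolate positive when either screening method is
positive; percentages are rendered to one decimal with half-up rounding,
matching the survey tables, and each emitted row satisfies
`positives = round(n · pct / 100)`. The association test is the two-sided
Fisher exact test in the minimum-likelihood convention (sum of
hypergeometric point probabilities not exceeding the observed table's,
with a 1e−7 relative tolerance for floating-point ties); the observed
morphology table passes the published bound under both the one- and
two-sided conventions, which the suite asserts. Coinfection reports the
mean (one decimal, half-up) and the midpoint median of per-host unique
virus counts over virus-positive sequenced hosts. TPM is
`10⁶ · (c_i/l_i) / Σ_j (c_j/l_j)` and always sums to 10⁶.

## Synthetic data: what it emulates, and what it does not

The generator plants back-translated family members (uniform random
synonymous codons, seeded) as stop-framed ORFs inside random-UTR contigs;
fragments keep the first or last half of the protein; mitovirus plants
write every tryptophan as TGA under table 4, guaranteeing an internal stop
under the standard code, with the family's single tryptophan frozen near
mid-domain so neither standard-code fragment reaches the census coverage
threshold yet both stay above the 100-residue ORF floor. Background
contigs are back-translated random proteins, so the scanner's negative
path sees genuine ORFs, not junk without reading frames. Endogenized
plants are copied verbatim into a 6-kb random genome. Reads tile templates
at uniform random starts with substitution errors and two-component
per-base qualities (70 % of reads uniformly Q30–40; 30 % carry 1–3 bases
at Q5–19), so the strict Q20 and loose Q5 filters genuinely differ.

Defaults: 60 hosts, 35 % infected, 1 + Poisson(1.2) viruses per infected
host (matching the survey's coinfection scale), 12 % mitovirus and 15 %
endogenization rates, 40 % fragment rate, 12 background contigs per host,
substitution rate 0 (the error-free setting in which recovery is provable).
These are the package's standing study conditions; tests may tighten or
perturb them but the defaults are not tuned per-test.

Deliberately not emulated: indels and quality-by-cycle error models,
realistic fungal gene structure (introns, UTR composition, codon bias),
assembly artifacts (chimeras, collapsed repeats), cross-host contamination,
and real RdRp sequence diversity — the synthetic families are random
proteins with a conserved G-D-D motif, far easier to separate than real
homologs. Passing the truth-recovery tests therefore demonstrates the
*logic* of the pipeline (gating, grouping, code switching, exclusion
rules), not sensitivity or specificity on real transcriptomes.

## Numerical choices and degenerate inputs

Alignment DP kernels run in compiled (numba) code with a shared Gotoh
recurrence; tracebacks are exact and tested against exhaustive path
enumeration on small instances. Gap costs follow the BLAST
existence/extension convention, `cost(L) = open + extend·L`. Local
alignments with no positive-scoring cell return an empty zero-score result;
`scan` and `classify` propagate that as "no hit". Empty FASTA files parse
to empty lists; empty censuses and all-zero contingency tables raise.
Seeds: every generator takes an explicit integer seed and is bit-for-bit
reproducible; the pipeline introduces no randomness of its own, so
re-running with identical inputs yields byte-identical reports.

## Problem sizes

The shipped drivers and the acceptance run use 50–60 hosts, ~770 contigs,
six profile families of 230–260 columns, and a ~20-reference panel; a full
run (generation + screening + census + statistics) completes in well under
a minute on one CPU core. These sizes were chosen as the smallest at which
every phenomenon of interest (all five branches, fragment pairs, mito
plants, endogenized plants, candidate rejection) occurs simultaneously.

## Known limitations

* The PSSM has no insert-state emission model; very gappy families would
  be served poorly (the synthetic families are ungapped-core by design).
* E-values use fixed gapped Karlin–Altschul parameters; they are not
  recomputed per scoring system.
* Extension is substitution-only and unpaired; it will not bridge indels
  or scaffold across gaps.
* The census trusts terminus classes from a single best hit per contig;
  multi-domain contigs (two RdRps on one contig) collapse to one call.
* Fixture-derived statistics reproduce printed aggregate figures; they do
  not, and cannot, re-derive the underlying per-isolate data.
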