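"""Synthetic survey generator: panels, rosters, transcriptomes, genomes, reads.

This module fabricates a complete, truth-annotated stand-in for the survey's
raw material so the whole pipeline can be exercised and verified end to end:

* a reference panel of aligned RdRp-like protein families (each carrying the
  invariant G-D-D catalytic motif) with labelled reference proteins, playing
  the role of the public profile and protein databases;
* a host roster with taxonomy from the survey's controlled vocabulary,
  developmental morphology, genome availability, and an in vitro screening
  column simulated consistently with the planted truth;
* per-host transcriptomes: ORF-bearing background contigs with no
  panel-derived content, plus planted viral contigs whose RdRp ORF is
  back-translated from a (possibly truncated, possibly mutated) panel family
  member — mitovirus plants use the mold-mitochondrial code with tryptophan
  written as TGA, so standard-code translation hits an internal stop;
* host genomes carrying verbatim copies of the endogenized plants and
  nothing derived from the exogenous ones;
* substitution-error reads with two-component per-base phred qualities, so
  the strict (Q20) and loose (Q5) filters genuinely differ.

Every generator is deterministic in its seed, and every planted virus is
recorded in a truth table against which pipeline output can be compared
exactly in the error-free setting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mycoscreen.codes import CODES, GeneticCode
from mycoscreen.config import Config
from mycoscreen.io import FastqRecord, read_tsv, write_fasta, write_tsv
from mycoscreen.panel import PanelRef, write_panel
from mycoscreen.roster import ORDERS, PHYLA, SUBPHYLA, HostIsolate, write_roster

AA20 = "ACDEFGHIKLMNPQRSTVWY"
AA_NO_W = AA20.replace("W", "")

COMPLETENESS = ("complete", "n_term", "c_term")


# ---------------------------------------------------------------------------
# panel


@dataclass(frozen=True)
class FamilySpec:
    name: str
    branch: str
    length: int
    is_mito: bool = False
    n_members: int = 8
    member_sub_rate: float = 0.10


#: The five Riboviria branches plus a mitovirus family (itself branch 1, the
#: levi/narna/ourmia-like clade). Lengths keep half-domain fragments above
#: the 100-residue ORF floor; the mitovirus tryptophan sits near mid-domain.
FAMILY_SPECS = (
    FamilySpec("fam_branch1", "1", 240),
    FamilySpec("fam_branch2", "2", 250),
    FamilySpec("fam_branch3", "3", 240),
    FamilySpec("fam_branch4", "4", 260),
    FamilySpec("fam_branch5", "5", 230),
    FamilySpec("fam_mito", "1", 230, is_mito=True),
)

#: G-D-D catalytic motif position as a fraction of family length.
MOTIF_FRACTION = 0.55
#: Mito-family tryptophan position (fraction); both standard-code fragments
#: of a mito plant then cover < 60% of the domain and stay >= 100 aa.
MITO_W_FRACTION = 0.45


@dataclass(frozen=True)
class Family:
    spec: FamilySpec
    alignment: tuple[tuple[str, str], ...]  # ungapped-core aligned members
    motif_col: int

    @property
    def name(self) -> str:
        return self.spec.name

    def member(self, member_id: str) -> str:
        for mid, seq in self.alignment:
            if mid == member_id:
                return seq
        raise KeyError(member_id)


@dataclass(frozen=True)
class PanelBundle:
    families: tuple[Family, ...]
    refs: tuple[PanelRef, ...]

    def family(self, name: str) -> Family:
        for fam in self.families:
            if fam.name == name:
                return fam
        raise KeyError(name)


def _random_protein(rng: np.random.Generator, length: int,
                    alphabet: str = AA20) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _mutate_protein(rng: np.random.Generator, protein: str, rate: float,
                    frozen_cols: set[int], alphabet: str = AA20) -> str:
    out = list(protein)
    for i in range(len(out)):
        if i in frozen_cols:
            continue
        if rng.random() < rate:
            choices = [a for a in alphabet if a != out[i]]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def gen_panel(seed: int) -> PanelBundle:
    """Generate the aligned family panel and labelled reference proteins.

    Every family sequence carries GDD at the designated motif columns; the
    mito family additionally carries a single mid-domain tryptophan (frozen
    in all members) and no tryptophan elsewhere.
    """
    rng = np.random.default_rng(seed)
    families = []
    refs: list[PanelRef] = []
    for spec in FAMILY_SPECS:
        alphabet = AA_NO_W if spec.is_mito else AA20
        consensus = list(_random_protein(rng, spec.length, alphabet))
        motif_col = int(MOTIF_FRACTION * spec.length)
        consensus[motif_col:motif_col + 3] = "GDD"
        frozen = {motif_col, motif_col + 1, motif_col + 2}
        if spec.is_mito:
            w_col = int(MITO_W_FRACTION * spec.length)
            consensus[w_col] = "W"
            frozen.add(w_col)
        consensus = "".join(consensus)
        members = []
        for m in range(spec.n_members):
            seq = _mutate_protein(rng, consensus, spec.member_sub_rate,
                                  frozen, alphabet)
            members.append((f"{spec.name}_m{m}", seq))
        families.append(Family(spec, tuple(members), motif_col))
        # first three members double as labelled references
        for mid, seq in members[:3]:
            refs.append(PanelRef(f"ref_{mid}", seq, spec.branch,
                                 is_viral=True, is_mitovirus=spec.is_mito))
    # non-viral decoys: host-like proteins unrelated to any family
    for d in range(4):
        refs.append(PanelRef(f"ref_decoy{d}", _random_protein(rng, 220),
                             "unassigned", is_viral=False, is_mitovirus=False))
    return PanelBundle(tuple(families), tuple(refs))


# ---------------------------------------------------------------------------
# planting


@dataclass
class PlantedVirus:
    member_id: str
    family: str
    branch: str
    completeness: str          # complete | n_term | c_term
    is_endogenous: bool
    uses_mito_code: bool
    contig_id: str = ""        # assigned by gen_transcriptome
    contig_seq: str = ""
    orf_span: tuple[int, int] = (0, 0)   # cds span within the contig
    genome_pos: int = -1       # insertion offset in the host genome


@dataclass
class TruthRecord:
    host_id: str
    planted: list[PlantedVirus] = field(default_factory=list)

    @property
    def exogenous(self) -> list[PlantedVirus]:
        return [p for p in self.planted if not p.is_endogenous]


def back_translate(protein: str, rng: np.random.Generator,
                   code: GeneticCode | str = "standard",
                   tga_for_trp: bool = False) -> str:
    """Back-translate with uniform random synonymous codons (seeded).

    ``tga_for_trp`` forces tryptophan to TGA — legal only under a code where
    TGA encodes Trp — which guarantees an internal stop under the standard
    code.
    """
    if isinstance(code, str):
        code = CODES[code]
    codons = []
    for aa in protein:
        if tga_for_trp and aa == "W":
            assert code.table["TGA"] == "W", "TGA is not Trp under this code"
            codons.append("TGA")
            continue
        options = code.codons_for(aa)
        if not options:
            raise ValueError(f"no codon for residue {aa!r}")
        codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@dataclass(frozen=True)
class TranscriptomeParams:
    n_host_contigs: int = 12
    host_orf_aa: tuple[int, int] = (110, 240)   # background ORF length range
    utr_nt: tuple[int, int] = (30, 90)
    viral_sub_rate: float = 0.0                 # protein-level substitutions
    frag_fraction: float = 0.5                  # span kept for fragments

    def __post_init__(self):
        if not 0.0 <= self.viral_sub_rate <= 0.2:
            raise ValueError("viral substitution rate must lie in [0, 0.2]")


def _orf_contig(rng: np.random.Generator, protein: str, code, tga_for_trp: bool,
                params: TranscriptomeParams) -> tuple[str, tuple[int, int]]:
    """Embed a back-translated protein as a stop-framed ORF with random UTRs."""
    cds = back_translate(protein, rng, code, tga_for_trp)
    left = _random_dna(rng, int(rng.integers(*params.utr_nt)))
    right = _random_dna(rng, int(rng.integers(*params.utr_nt)))
    seq = left + "TAA" + cds + "TAA" + right
    start = len(left) + 3
    return seq, (start, start + len(cds))


def gen_transcriptome(host: HostIsolate, truth: TruthRecord,
                      panel: PanelBundle, params: TranscriptomeParams,
                      seed: int) -> list[tuple[str, str]]:
    """Host transcriptome: background contigs plus the planted viral contigs.

    Mutates ``truth`` in place, assigning each plant its contig id, contig
    sequence, and cds span.
    """
    rng = np.random.default_rng(seed)
    contigs: list[tuple[str, str]] = []
    for i in range(params.n_host_contigs):
        length = int(rng.integers(*params.host_orf_aa))
        protein = _random_protein(rng, length)
        seq, _ = _orf_contig(rng, protein, "standard", False, params)
        contigs.append((f"{host.id}|c{i:03d}", seq))
    for j, plant in enumerate(truth.planted):
        member = panel.family(plant.family).member(plant.member_id)
        frac = params.frag_fraction
        if plant.completeness == "n_term":
            protein = member[:int(len(member) * frac)]
        elif plant.completeness == "c_term":
            protein = member[len(member) - int(len(member) * frac):]
        else:
            protein = member
        if params.viral_sub_rate > 0:
            protein = _mutate_protein(rng, protein, params.viral_sub_rate,
                                      set(), AA_NO_W if plant.uses_mito_code
                                      else AA20)
        code = "mito" if plant.uses_mito_code else "standard"
        seq, span = _orf_contig(rng, protein, code, plant.uses_mito_code,
                                params)
        plant.contig_id = f"{host.id}|v{j:02d}"
        plant.contig_seq = seq
        plant.orf_span = span
        contigs.append((plant.contig_id, seq))
    return contigs


# ---------------------------------------------------------------------------
# reads


def gen_reads(template: str, depth: int, read_len: int, error_rate: float,
              seed: int, id_prefix: str = "read") -> list[FastqRecord]:
    """Uniform substitution-error reads over a template, phred+33 qualities.

    Per-base phreds come from a two-component mixture: 70% of reads are
    uniformly high quality (Q30-40), 30% carry a handful of low-quality
    bases (Q5-19), so a strict Q20 minimum filter removes them while the
    loose Q5 filter keeps everything.
    """
    if read_len > len(template):
        raise ValueError("read_len exceeds template length")
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must lie in [0, 0.1]")
    rng = np.random.default_rng(seed)
    n_reads = math.ceil(depth * len(template) / read_len)
    reads = []
    for i in range(n_reads):
        start = int(rng.integers(0, len(template) - read_len + 1))
        bases = list(template[start:start + read_len])
        for b in range(read_len):
            if error_rate > 0 and rng.random() < error_rate:
                choices = [x for x in "ACGT" if x != bases[b]]
                bases[b] = choices[int(rng.integers(3))]
        if rng.random() < 0.7:
            quals = rng.integers(30, 41, size=read_len)
        else:
            quals = rng.integers(30, 41, size=read_len)
            n_bad = int(rng.integers(1, 4))
            bad_pos = rng.choice(read_len, size=n_bad, replace=False)
            quals[bad_pos] = rng.integers(5, 20, size=n_bad)
        qual = "".join(chr(int(q) + 33) for q in quals)
        reads.append(FastqRecord(f"{id_prefix}_{i}", "".join(bases), qual))
    return reads


# ---------------------------------------------------------------------------
# genomes


def gen_genome(host: HostIsolate, truth: TruthRecord, seed: int,
               background_nt: int = 6000) -> str | None:
    """Host (or relative) genome with verbatim copies of endogenized plants.

    Returns None when the host has no genome. Exogenous plants contribute
    nothing to the genome.
    """
    if host.genome_available == "none":
        return None
    rng = np.random.default_rng(seed)
    genome = _random_dna(rng, background_nt)
    for plant in truth.planted:
        if not plant.is_endogenous:
            continue
        if not plant.contig_seq:
            raise ValueError(
                f"plant {plant.member_id} for {host.id}: generate the "
                "transcriptome before the genome")
        pos = int(rng.integers(0, len(genome)))
        genome = genome[:pos] + plant.contig_seq + genome[pos:]
        plant.genome_pos = pos
    return genome


# ---------------------------------------------------------------------------
# whole survey


@dataclass(frozen=True)
class SurveyParams:
    n_hosts: int = 60
    infection_prob: float = 0.35      # fraction of hosts with >= 1 plant
    extra_virus_mean: float = 1.2     # Poisson mean beyond the first virus
    mito_prob: float = 0.12           # chance a plant is a mitovirus
    endo_prob: float = 0.15           # chance a plant is endogenized
    fragment_prob: float = 0.4        # chance a non-mito plant is a fragment
    in_vitro_prob: float = 0.6        # fraction of hosts screened in vitro
    genome_probs: tuple[float, float, float] = (0.35, 0.15, 0.50)  # own/rel/none
    transcriptome: TranscriptomeParams = TranscriptomeParams()


@dataclass(frozen=True)
class SurveyBundle:
    roster: tuple[HostIsolate, ...]
    truths: tuple[TruthRecord, ...]
    panel: PanelBundle
    contigs: tuple[tuple[str, str], ...]      # all hosts, roster order
    genomes: dict  # host_id -> genome string

    def truth_for(self, host_id: str) -> TruthRecord:
        for t in self.truths:
            if t.host_id == host_id:
                return t
        raise KeyError(host_id)


def _sample_taxon(rng: np.random.Generator) -> tuple[str, str, str, str]:
    phylum = PHYLA[int(rng.integers(len(PHYLA)))]
    subphylum = ""
    order = ""
    if phylum in SUBPHYLA:
        subphylum = SUBPHYLA[phylum][int(rng.integers(len(SUBPHYLA[phylum])))]
    if phylum in ORDERS:
        order = ORDERS[phylum][int(rng.integers(len(ORDERS[phylum])))]
    zoosporic = phylum in ("Chytridiomycota", "Blastocladiomycota",
                           "Neocallimastigomycota")
    if zoosporic:
        morphology = "polycentric" if rng.random() < 0.3 else "monocentric"
    else:
        morphology = "unknown"
    return phylum, subphylum, order, morphology


def gen_survey(params: SurveyParams, seed: int) -> SurveyBundle:
    """Generate a full truth-annotated survey bundle.

    The in vitro screening column is filled, error-free, from the planted
    truth (positive iff the host carries at least one exogenous plant) for
    the sampled fraction of hosts; the in silico column is left ``not_done``
    for the pipeline to fill.
    """
    rng = np.random.default_rng(seed)
    mito_fam = next(f for f in FAMILY_SPECS if f.is_mito)
    std_fams = [f for f in FAMILY_SPECS if not f.is_mito]
    panel = gen_panel(int(rng.integers(2**31)))
    roster: list[HostIsolate] = []
    truths: list[TruthRecord] = []
    contigs: list[tuple[str, str]] = []
    genomes: dict[str, str] = {}
    for h in range(params.n_hosts):
        host_id = f"H{h:03d}"
        phylum, subphylum, order, morphology = _sample_taxon(rng)
        genome_available = ("own", "relative", "none")[
            int(rng.choice(3, p=params.genome_probs))]
        truth = TruthRecord(host_id)
        if rng.random() < params.infection_prob:
            n_viruses = 1 + int(rng.poisson(params.extra_virus_mean))
            for _ in range(n_viruses):
                is_mito = rng.random() < params.mito_prob
                spec = mito_fam if is_mito else \
                    std_fams[int(rng.integers(len(std_fams)))]
                fam = panel.family(spec.name)
                member_id = fam.alignment[
                    int(rng.integers(len(fam.alignment)))][0]
                if is_mito:
                    completeness = "complete"
                elif rng.random() < params.fragment_prob:
                    completeness = ("n_term", "c_term")[int(rng.integers(2))]
                else:
                    completeness = "complete"
                is_endo = (genome_available != "none"
                           and rng.random() < params.endo_prob)
                truth.planted.append(PlantedVirus(
                    member_id=member_id, family=spec.name, branch=spec.branch,
                    completeness=completeness, is_endogenous=is_endo,
                    uses_mito_code=is_mito))
        in_vitro = "not_done"
        if rng.random() < params.in_vitro_prob:
            in_vitro = "positive" if truth.exogenous else "negative"
        host = HostIsolate(host_id, phylum, subphylum, order, morphology,
                           in_vitro_result=in_vitro,
                           genome_available=genome_available)
        contigs.extend(gen_transcriptome(host, truth, panel,
                                         params.transcriptome,
                                         int(rng.integers(2**31))))
        genome = gen_genome(host, truth, int(rng.integers(2**31)))
        if genome is not None:
            genomes[host_id] = genome
        roster.append(host)
        truths.append(truth)
    return SurveyBundle(tuple(roster), tuple(truths), panel,
                        tuple(contigs), genomes)


# ---------------------------------------------------------------------------
# expected (truth-derived) pipeline outcomes, error-free setting


def expected_positive(truth: TruthRecord) -> bool:
    """Expected isolate-level in silico call for the exogenous census."""
    return bool(truth.exogenous)


def expected_unique_virus_count(truth: TruthRecord,
                                cfg: Config | None = None) -> int:
    """Unique-virus count the conservative criteria should yield.

    Derived purely from planted attributes: a complete plant covers the whole
    domain, a fragment covers ``frag_fraction`` of it. Grouping and the
    coverage / concatenation rules then follow the census criteria.
    """
    cfg = cfg or Config()
    frac = TranscriptomeParams().frag_fraction
    by_branch: dict[str, list[PlantedVirus]] = {}
    for p in truth.exogenous:
        by_branch.setdefault(p.branch, []).append(p)
    count = 0
    for group in by_branch.values():
        if len(group) == 1:
            count += 1
            continue
        termini = sorted(p.completeness for p in group)
        if len(group) == 2 and termini == ["c_term", "n_term"]:
            count += 1
            continue
        coverages = [1.0 if p.completeness == "complete" else frac
                     for p in group]
        passing = sum(c > cfg.coverage_threshold for c in coverages)
        count += passing if passing else 1
    return count


# ---------------------------------------------------------------------------
# on-disk bundle


def write_bundle(bundle: SurveyBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write roster/truth/contigs/genomes/panel to a directory; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "roster": out / "roster.tsv",
        "truth": out / "truth.tsv",
        "contigs": out / "contigs.fasta",
        "genomes": out / "genomes.fasta",
        "panel": out / "panel",
    }
    write_roster(paths["roster"], list(bundle.roster))
    write_tsv(paths["truth"],
              ["host_id", "contig_id", "member_id", "family", "branch",
               "completeness", "is_endogenous", "uses_mito_code"],
              ([t.host_id, p.contig_id, p.member_id, p.family, p.branch,
                p.completeness, int(p.is_endogenous), int(p.uses_mito_code)]
               for t in bundle.truths for p in t.planted))
    write_fasta(paths["contigs"], list(bundle.contigs))
    write_fasta(paths["genomes"], sorted(bundle.genomes.items()))
    paths["panel"].mkdir(exist_ok=True)
    write_panel(paths["panel"] / "references.fasta", list(bundle.panel.refs))
    for fam in bundle.panel.families:
        write_fasta(paths["panel"] / f"{fam.name}.afa", list(fam.alignment))
    return paths


def read_truth(path: str | Path) -> list[TruthRecord]:
    header, rows = read_tsv(path)
    truths: dict[str, TruthRecord] = {}
    for row in rows:
        rec = dict(zip(header, row))
        truths.setdefault(rec["host_id"], TruthRecord(rec["host_id"]))
        truths[rec["host_id"]].planted.append(PlantedVirus(
            member_id=rec["member_id"], family=rec["family"],
            branch=rec["branch"], completeness=rec["completeness"],
            is_endogenous=rec["is_endogenous"] == "1",
            uses_mito_code=rec["uses_mito_code"] == "1",
            contig_id=rec["contig_id"]))
    return list(truths.values())
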