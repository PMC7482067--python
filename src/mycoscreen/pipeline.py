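"""End-to-end orchestration of the in silico screening pipeline.

Stages, mirroring the survey's protocol: six-frame ORF prediction on every
contig (standard code), PSSM profile scan for RdRp-like regions, reference
panel confirmation under the E-value gate (with mitochondrial-code
retranslation when the best reference is a mitovirus), endogeny screening
against the host or relative genome, optional read-based contig extension,
per-host census by the conservative criteria, and the survey statistics.

Reports are TSV with header rows; coordinates in reports are 1-based
inclusive, while all internal types stay 0-based half-open. Given the same
inputs and config the emitted reports are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from mycoscreen.census import CensusEntry, VirusCall, dedup, screen_call
from mycoscreen.classify import ReferenceHit, classify
from mycoscreen.codes import MITO, STANDARD
from mycoscreen.config import Config
from mycoscreen.endogeny import EndogenyCall, endogeny_call, genome_match
from mycoscreen.extension import ExtensionResult, extend_contig, filter_reads
from mycoscreen.io import read_fasta, read_fastq, write_tsv
from mycoscreen.orfs import find_orfs
from mycoscreen.panel import PanelRef, read_panel
from mycoscreen.pssm import Profile, ProfileHit, build_profile, scan
from mycoscreen.roster import HostIsolate, read_roster, write_roster
from mycoscreen.stats import (Contingency2x2, coinfection_summary,
                              fisher_exact, method_agreement,
                              prevalence_table)


@dataclass(frozen=True)
class ContigResult:
    """Everything the pipeline decided about one contig."""
    contig_id: str
    host_id: str
    profile_hit: ProfileHit | None
    reference_hit: ReferenceHit | None
    endogeny: EndogenyCall | None
    call: VirusCall | None
    uses_mito_code: bool = False


@dataclass
class PipelineResult:
    config: Config
    roster: list[HostIsolate]
    contig_results: list[ContigResult]
    census: dict[str, CensusEntry] = field(default_factory=dict)
    screen: dict[str, str] = field(default_factory=dict)
    extensions: list[ExtensionResult] = field(default_factory=list)

    @property
    def calls(self) -> list[VirusCall]:
        return [r.call for r in self.contig_results if r.call is not None]


def host_of(contig_id: str) -> str:
    """Contig ids are ``<host>|<name>``; the prefix is the host id."""
    return contig_id.split("|", 1)[0]


def build_profiles(families: dict[str, list[tuple[str, str]]],
                   pseudocount: float = 1.0) -> list[Profile]:
    return [build_profile(aln, pseudocount=pseudocount, name=name)
            for name, aln in sorted(families.items())]


def _best_scan(protein, profiles: list[Profile], cfg: Config, orf):
    best: ProfileHit | None = None
    for profile in profiles:
        hit = scan(protein, profile, min_bits=cfg.profile_hit_bits, orf=orf)
        if hit and (best is None or hit.bit_score > best.bit_score):
            best = hit
    return best


def _scan_one_code(contig_seq: str, contig_id: str, profiles, panel, cfg,
                   code) -> tuple[ProfileHit | None, ReferenceHit | None]:
    """Best profile hit and best confirmed reference hit under one code."""
    pairs: list[tuple[ProfileHit, ReferenceHit | None]] = []
    for orf in find_orfs(contig_seq, cfg.min_orf_aa, code, contig_id):
        phit = _best_scan(orf.protein, profiles, cfg, orf)
        if phit is None:
            continue
        pairs.append((phit, classify(phit, panel, cfg)))
    if not pairs:
        return None, None
    confirmed = [(p, r) for p, r in pairs if r is not None]
    if confirmed:
        # the call's coverage comes from the ORF whose hit was confirmed
        return max(confirmed, key=lambda pr: pr[1].score)
    return max(pairs, key=lambda pr: pr[0].bit_score)


def screen_contig(contig_id: str, contig_seq: str, profiles: list[Profile],
                  panel: list[PanelRef], cfg: Config,
                  genome: str | None = None,
                  genome_provenance: str = "none") -> ContigResult:
    """Scan, confirm, optionally retranslate (mitovirus), and endogeny-check."""
    host = host_of(contig_id)
    phit, rhit = _scan_one_code(contig_seq, contig_id, profiles, panel, cfg,
                                STANDARD)
    uses_mito = False
    if rhit is not None and rhit.is_mitovirus:
        mito_phit, mito_rhit = _scan_one_code(contig_seq, contig_id, profiles,
                                              panel, cfg, MITO)
        # keep the retranslated result when it recovers at least as much
        if mito_rhit is not None and mito_rhit.score >= rhit.score:
            phit, rhit, uses_mito = mito_phit, mito_rhit, True
    if phit is None:
        return ContigResult(contig_id, host, None, None, None, None)
    endo: EndogenyCall | None = None
    if genome is not None and genome_provenance != "none":
        match = genome_match(contig_seq, genome)
        endo = endogeny_call(contig_id, match, genome_provenance, cfg)
    else:
        endo = endogeny_call(contig_id, None, "none", cfg)
    call = VirusCall(
        contig_id=contig_id,
        host_id=host,
        branch=rhit.branch if rhit else "unassigned",
        coverage=phit.coverage,
        terminus_class=phit.terminus_class,
        endogeny_status=endo.status,
        confirmed=rhit is not None,
        contig_len=len(contig_seq),
        uses_mito_code=uses_mito,
    )
    return ContigResult(contig_id, host, phit, rhit, endo, call, uses_mito)


def run_pipeline(cfg: Config, roster_path, contigs_path, panel_path,
                 genomes_path=None, reads_path=None, out_dir=None,
                 include_candidates: bool = False) -> PipelineResult:
    """Run every stage over an on-disk bundle and emit the report TSVs.

    ``panel_path`` is a directory holding ``references.fasta`` and one
    aligned FASTA (``*.afa``) per family. ``reads_path``, when given, feeds
    loose-filtered reads to the extension stage for every confirmed viral
    contig. Deterministic: identical inputs yield byte-identical reports.
    """
    roster = read_roster(roster_path)
    by_id = {h.id: h for h in roster}
    contigs = read_fasta(contigs_path, alphabet="dna")
    orphans = sorted({host_of(cid) for cid, _ in contigs} - set(by_id))
    if orphans:
        raise ValueError(f"contig host ids missing from roster: {orphans}")

    panel_dir = Path(panel_path)
    panel = read_panel(panel_dir / "references.fasta")
    families = {p.stem: read_fasta(p, alphabet="aligned")
                for p in sorted(panel_dir.glob("*.afa"))}
    profiles = build_profiles(families)

    genomes: dict[str, str] = {}
    if genomes_path and Path(genomes_path).exists():
        genomes = {rid.split()[0]: seq
                   for rid, seq in read_fasta(genomes_path, alphabet="dna")}

    results: list[ContigResult] = []
    for cid, seq in contigs:
        host = by_id[host_of(cid)]
        genome = genomes.get(host.id)
        provenance = host.genome_available if genome is not None else "none"
        results.append(screen_contig(cid, seq, profiles, panel, cfg,
                                     genome, provenance))

    res = PipelineResult(cfg, roster, results)

    # extension of confirmed viral contigs from loose-filtered reads
    if reads_path and Path(reads_path).exists():
        reads = filter_reads(read_fastq(reads_path), cfg.min_phred_loose)
        contig_seqs = dict(contigs)
        for r in results:
            if r.call is not None and r.call.confirmed:
                res.extensions.append(
                    extend_contig(contig_seqs[r.contig_id], reads, cfg,
                                  seed_id=r.contig_id))

    # per-host census and isolate-level calls; fill in_silico on the roster
    calls_by_host: dict[str, list[VirusCall]] = {h.id: [] for h in roster}
    for r in results:
        if r.call is not None:
            calls_by_host[r.host_id].append(r.call)
    roster_out: list[HostIsolate] = []
    for h in roster:
        calls = calls_by_host[h.id]
        verdict = screen_call(calls, cfg, include_candidates)
        res.screen[h.id] = verdict
        res.census[h.id] = dedup(calls, cfg, include_candidates)
        roster_out.append(replace(h, in_silico_result=verdict))
    res.roster = roster_out

    if out_dir is not None:
        write_reports(res, out_dir)
    return res


def _fmt(x: float) -> str:
    return f"{x:.4g}"


def write_reports(res: PipelineResult, out_dir) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    rows = []
    for r in sorted(res.contig_results, key=lambda x: x.contig_id):
        if r.profile_hit is None:
            continue
        p, h = r.profile_hit, r.reference_hit
        rows.append([
            r.contig_id, r.host_id, p.profile_name, _fmt(p.bit_score),
            p.c_start + 1, p.c_end, f"{p.coverage:.4f}", p.terminus_class,
            h.reference_id if h else ".", _fmt(h.evalue) if h else ".",
            h.branch if h else "unassigned", int(h is not None),
            r.endogeny.status if r.endogeny else "unknown",
            int(r.uses_mito_code),
        ])
    paths["hits"] = out / "hits.tsv"
    write_tsv(paths["hits"],
              ["contig_id", "host_id", "profile", "bit_score",
               "profile_start", "profile_end", "coverage", "terminus",
               "reference_id", "evalue", "branch", "confirmed",
               "endogeny", "mito_code"], rows)

    rows = []
    for host_id in sorted(res.census):
        for i, v in enumerate(res.census[host_id].viruses, 1):
            rows.append([host_id, i, v.branch, ",".join(v.member_contigs),
                        f"{v.coverage:.4f}", int(v.concatenated)])
    paths["census"] = out / "census.tsv"
    write_tsv(paths["census"],
              ["host_id", "virus_index", "branch", "member_contigs",
               "coverage", "concatenated"], rows)

    for rank in ("phylum", "subphylum", "order"):
        paths[rank] = out / f"prevalence_{rank}.tsv"
        write_tsv(paths[rank], ["taxon", "rank", "n", "positives", "pct"],
                  ([r.taxon, r.rank, r.n, r.positives, f"{r.pct:.1f}"]
                   for r in prevalence_table(res.roster, rank)))

    counts = [e.n_viruses for e in res.census.values() if e.n_viruses > 0]
    paths["coinfection"] = out / "coinfection.tsv"
    if counts:
        mean, median = coinfection_summary(counts)
        write_tsv(paths["coinfection"],
                  ["positive_hosts", "unique_viruses", "mean", "median"],
                  [[len(counts), sum(counts), f"{mean:.1f}", f"{median:.1f}"]])
    else:
        write_tsv(paths["coinfection"],
                  ["positive_hosts", "unique_viruses", "mean", "median"],
                  [[0, 0, ".", "."]])

    both = [h for h in res.roster if h.in_vitro_result != "not_done"
            and h.in_silico_result != "not_done"]
    paths["agreement"] = out / "agreement.tsv"
    write_tsv(paths["agreement"], ["n_both", "pct_concordant"],
              [[len(both),
                f"{method_agreement(res.roster):.1f}" if both else "."]])

    poly = [h for h in res.roster if h.morphology == "polycentric"]
    mono = [h for h in res.roster if h.morphology == "monocentric"]
    paths["association"] = out / "association.tsv"
    if poly and mono:
        t = Contingency2x2(
            sum(h.combined_positive for h in poly),
            sum(not h.combined_positive for h in poly),
            sum(h.combined_positive for h in mono),
            sum(not h.combined_positive for h in mono))
        write_tsv(paths["association"],
                  ["poly_pos", "poly_neg", "mono_pos", "mono_neg", "fisher_p"],
                  [[t.a, t.b, t.c, t.d, _fmt(fisher_exact(t))]])
    else:
        write_tsv(paths["association"],
                  ["poly_pos", "poly_neg", "mono_pos", "mono_neg", "fisher_p"],
                  [[len(poly), 0, len(mono), 0, "."]])

    if res.extensions:
        paths["extension"] = out / "extension.tsv"
        write_tsv(paths["extension"],
                  ["contig_id", "final_len", "cycles", "blocks", "status"],
                  ([e.seed_id, len(e.sequence), e.cycles_run, e.blocks_run,
                    e.status] for e in res.extensions))

    paths["roster"] = out / "roster_screened.tsv"
    write_roster(paths["roster"], res.roster)
    return paths
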