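"""Isolate-level infection calls and conservative unique-virus deduplication.

Assembled viromes are frequently fragmented, so counting contigs would
over-report viruses. The census applies conservative per-host criteria,
grouping a host's confirmed exogenous calls by Riboviria branch:

* a branch with a single contig contributes one virus;
* a branch with exactly one N-terminal and one C-terminal RdRp fragment is
  treated as one virus assembled in two pieces (the fragments are
  concatenated);
* otherwise every contig covering more than ``coverage_threshold`` (default
  60%) of the RdRp domain counts as its own virus, and if none does, only the
  highest-coverage contig is kept (ties: longer contig, then smaller id).

Coverage exactly at the threshold does NOT pass (a strict reading of ">60%").
"""

from __future__ import annotations

from dataclasses import dataclass, field

from mycoscreen.config import Config
from mycoscreen.panel import BRANCHES


@dataclass(frozen=True)
class VirusCall:
    contig_id: str
    host_id: str
    branch: str
    coverage: float
    terminus_class: str     # complete | n_term | c_term | internal
    endogeny_status: str    # exogenous | endogenous | likely_endogenous | unknown
    confirmed: bool         # passed the reference E-value gate
    contig_len: int = 0
    uses_mito_code: bool = False

    def __post_init__(self):
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError(f"coverage must lie in (0, 1], got {self.coverage}")
        if self.branch not in BRANCHES:
            raise ValueError(f"unknown branch {self.branch!r}")


@dataclass(frozen=True)
class UniqueVirus:
    member_contigs: tuple[str, ...]
    branch: str
    coverage: float   # representative coverage (see dedup)
    concatenated: bool


@dataclass(frozen=True)
class CensusEntry:
    host_id: str
    viruses: tuple[UniqueVirus, ...] = field(default_factory=tuple)

    @property
    def n_viruses(self) -> int:
        return len(self.viruses)


def _censusable(call: VirusCall, include_candidates: bool) -> bool:
    # "unknown" (no genome to check) is treated as exogenous, as in the
    # survey, where the genome check ran only when a genome existed.
    if call.endogeny_status not in ("exogenous", "unknown"):
        return False
    return call.confirmed or include_candidates


def screen_call(calls: list[VirusCall], cfg: Config,
                include_candidates: bool = False) -> str:
    """Isolate-level in silico screening result: 'positive' or 'negative'.

    Positive iff the host has at least one confirmed, non-endogenous call
    (contigs without a genome to check count: absence of a genome never
    rescued a negative in the survey). Unconfirmed candidates count only when
    explicitly included.
    """
    hosts = {c.host_id for c in calls}
    if len(hosts) > 1:
        raise ValueError(f"calls span multiple hosts: {sorted(hosts)}")
    for call in calls:
        if _censusable(call, include_candidates):
            return "positive"
    return "negative"


def dedup(calls: list[VirusCall], cfg: Config,
          include_candidates: bool = False) -> CensusEntry:
    """Reduce one host's calls to unique viruses by the conservative criteria."""
    hosts = {c.host_id for c in calls}
    if len(hosts) > 1:
        raise ValueError(f"calls span multiple hosts: {sorted(hosts)}")
    host_id = hosts.pop() if hosts else ""
    usable = [c for c in calls if _censusable(c, include_candidates)]
    by_branch: dict[str, list[VirusCall]] = {}
    for call in usable:
        by_branch.setdefault(call.branch, []).append(call)
    viruses: list[UniqueVirus] = []
    for branch in sorted(by_branch):
        group = sorted(by_branch[branch], key=lambda c: c.contig_id)
        if len(group) == 1:
            c = group[0]
            viruses.append(UniqueVirus((c.contig_id,), branch, c.coverage, False))
            continue
        termini = sorted(c.terminus_class for c in group)
        if len(group) == 2 and termini == ["c_term", "n_term"]:
            cov = min(1.0, sum(c.coverage for c in group))
            viruses.append(UniqueVirus(tuple(c.contig_id for c in group),
                                       branch, cov, True))
            continue
        passing = [c for c in group if c.coverage > cfg.coverage_threshold]
        if passing:
            for c in passing:
                viruses.append(UniqueVirus((c.contig_id,), branch,
                                           c.coverage, False))
        else:
            keep = max(group, key=lambda c: (c.coverage, c.contig_len,
                                             _rev_id(c.contig_id)))
            viruses.append(UniqueVirus((keep.contig_id,), branch,
                                       keep.coverage, False))
    return CensusEntry(host_id, tuple(viruses))


class _rev_id(str):
    """Reverses string ordering so max() prefers the lexicographically
    smaller id on full ties."""

    def __lt__(self, other):  # max picks the "largest" => smallest id
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)
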