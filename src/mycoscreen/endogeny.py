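"""Endogenization screen: is a viral contig also present in the host genome?

A transcript matching the host's own DNA genome at high nucleotide identity is
an endogenized virus-like element, transcribed but not an exogenous infection,
and is excluded from the exogenous census. When only a close relative's genome
is available a passing match yields "likely_endogenous" rather than a firm
call, and hosts with no genome at all stay "unknown".

Matching is k-mer-seeded: shared words (default k=11) between contig and
genome (both strands) localise a genome window, and a local nucleotide
alignment (match +1, mismatch -1, gap -2) inside that window reports the best
match by aligned length x identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mycoscreen.align import align_local
from mycoscreen.config import Config
from mycoscreen.orfs import revcomp

_NT_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
MATCH, MISMATCH, GAP = 1.0, -1.0, 2.0  # gap cost per nt (linear)

STATUSES = ("exogenous", "endogenous", "likely_endogenous", "unknown")


@dataclass(frozen=True)
class GenomeMatch:
    identity: float     # matches / alignment columns
    aligned_len: int    # alignment columns
    contig_span: tuple[int, int]
    genome_span: tuple[int, int]
    strand: str


@dataclass(frozen=True)
class EndogenyCall:
    contig_id: str
    status: str
    match: GenomeMatch | None
    genome_provenance: str  # own | relative | none


def _nt_scores(a: str, b: str) -> np.ndarray:
    ai = np.array([_NT_INDEX.get(c, 4) for c in a.upper()])
    bi = np.array([_NT_INDEX.get(c, 4) for c in b.upper()])
    S = np.where(ai[:, None] == bi[None, :], MATCH, MISMATCH)
    S[ai == 4, :] = MISMATCH  # N never counts as a match
    S[:, bi == 4] = MISMATCH
    return S


def _seed_windows(contig: str, genome: str, k: int) -> list[tuple[int, int]]:
    """Genome windows implied by shared k-mer diagonals, merged."""
    index: dict[str, list[int]] = {}
    for j in range(len(genome) - k + 1):
        index.setdefault(genome[j:j + k], []).append(j)
    hits = []
    for i in range(len(contig) - k + 1):
        for j in index.get(contig[i:i + k], ()):
            hits.append(j - i)  # diagonal = genome offset of contig start
    if not hits:
        return []
    pad = len(contig)
    windows = []
    for d in sorted(set(hits)):
        lo = max(0, d - pad // 2)
        hi = min(len(genome), d + len(contig) + pad // 2)
        if windows and lo <= windows[-1][1]:
            windows[-1] = (windows[-1][0], max(windows[-1][1], hi))
        else:
            windows.append((lo, hi))
    return windows


def genome_match(contig: str, genome: str, k: int = 11) -> GenomeMatch | None:
    """Best local nucleotide match of contig against genome, both strands.

    Returns None when contig and genome share no k-mer. Requires k >= 8.
    """
    if k < 8:
        raise ValueError("seed word size k must be >= 8")
    contig, genome = contig.upper(), genome.upper()
    if len(contig) < k or len(genome) < k:
        return None
    best: GenomeMatch | None = None
    for strand in ("+", "-"):
        query = contig if strand == "+" else revcomp(contig)
        for lo, hi in _seed_windows(query, genome, k):
            S = _nt_scores(query, genome[lo:hi])
            aln = align_local(S, 0.0, GAP)
            if not aln.ops:
                continue
            matches = sum(1 for op, i, j in aln.ops
                          if op == "M" and query[i] == genome[lo + j])
            identity = matches / len(aln.ops)
            cand = GenomeMatch(
                identity=identity,
                aligned_len=len(aln.ops),
                contig_span=(aln.q_start, aln.q_end),
                genome_span=(lo + aln.t_start, lo + aln.t_end),
                strand=strand,
            )
            rank = (cand.aligned_len * cand.identity, cand.identity)
            if best is None or rank > (best.aligned_len * best.identity,
                                       best.identity):
                best = cand
    return best


def endogeny_call(contig_id: str, match: GenomeMatch | None,
                  provenance: str, cfg: Config) -> EndogenyCall:
    """Classify a contig as exogenous / endogenous / likely_endogenous / unknown.

    A match passes when identity >= cfg.endo_identity over at least
    cfg.endo_min_len_nt aligned columns. With a passing match the call is
    "endogenous" against the host's own genome and "likely_endogenous"
    against a relative's; without a genome the call is "unknown".
    """
    if provenance not in ("own", "relative", "none"):
        raise ValueError(f"unknown genome provenance {provenance!r}")
    if provenance == "none":
        return EndogenyCall(contig_id, "unknown", None, provenance)
    passing = (match is not None
               and match.identity >= cfg.endo_identity
               and match.aligned_len >= cfg.endo_min_len_nt)
    if passing:
        status = "endogenous" if provenance == "own" else "likely_endogenous"
    else:
        status = "exogenous"
    return EndogenyCall(contig_id, status, match if passing else match, provenance)
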