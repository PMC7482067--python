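"""Iterative seed-based contig extension from reads, with the phred filter.

This re-creates, at desk scale, the PRICE-style protocol used to improve
viral contigs: loosely quality-filtered reads that overlap a contig end by at
least ``min_overlap_nt`` bases at ``edge_identity`` identity — and whose
within-contig portion stays ``seed_identity``-identical to the original seed
over the region where they overlap it — vote base-by-base on the overhang.
Overhang positions supported by at least two reads are appended by majority
vote; a tie truncates the overhang at that position. Cycles run in blocks of
``cycles_per_block``; a block that leaves the contig unchanged ends the
procedure ("complete"), otherwise the updated contig seeds a new block, up to
``max_blocks``.

Read-to-end matching is ungapped (substitution-only reads are simulated, and
the protocol's identity thresholds are fractions of overlap length).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from mycoscreen.config import Config
from mycoscreen.io import FastqRecord
from mycoscreen.orfs import revcomp

MIN_OVERHANG_SUPPORT = 2


@dataclass(frozen=True)
class ExtensionResult:
    seed_id: str
    sequence: str
    cycles_run: int
    blocks_run: int
    status: str  # complete | max_blocks_reached
    block_changed: tuple[bool, ...] = field(default_factory=tuple)


def filter_reads(reads: list[FastqRecord], min_phred: int) -> list[FastqRecord]:
    """Keep reads whose minimum per-base quality is >= ``min_phred``."""
    kept = []
    for r in reads:
        if len(r.qual) != len(r.seq):
            raise ValueError(f"read {r.id}: quality/sequence length mismatch")
        if not r.seq or min(r.phred()) >= min_phred:
            kept.append(r)
    return kept


def _identity(a: str, b: str) -> float:
    assert len(a) == len(b)
    if not a:
        return 1.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def _end_votes(contig: str, seed: str, seed_offset: int, reads: list[str],
               cfg: Config, side: str) -> list[dict[str, int]]:
    """Per-overhang-position base votes from reads anchored at one end.

    ``side`` is 'right' or 'left'; for 'left' the overhang grows leftwards and
    votes[0] is the position immediately left of the contig.
    """
    n = len(contig)
    votes: list[dict[str, int]] = []
    for read in reads:
        L = len(read)
        best = None  # (identity, olap, overhang)
        # olap = number of read bases overlapping the contig
        for olap in range(cfg.min_overlap_nt, min(L - 1, n) + 1):
            if side == "right":
                read_in, read_out = read[:olap], read[olap:]
                contig_part = contig[n - olap:]
                in_start = n - olap
            else:
                read_out, read_in = read[:L - olap], read[L - olap:]
                contig_part = contig[:olap]
                in_start = 0
            ident = _identity(read_in, contig_part)
            if ident < cfg.edge_identity:
                continue
            # agreement of the within-contig portion with the ORIGINAL seed
            s0 = max(in_start, seed_offset)
            s1 = min(in_start + olap, seed_offset + len(seed))
            if s1 > s0:
                read_seg = read_in[s0 - in_start:s1 - in_start]
                seed_seg = seed[s0 - seed_offset:s1 - seed_offset]
                if _identity(read_seg, seed_seg) < cfg.seed_identity:
                    continue
            if best is None or (ident, olap) > best[:2]:
                best = (ident, olap, read_out)
        if best is None:
            continue
        overhang = best[2] if side == "right" else best[2][::-1]
        # for 'left', overhang position 0 is the base adjacent to the contig
        for pos, base in enumerate(overhang):
            while len(votes) <= pos:
                votes.append({})
            votes[pos][base] = votes[pos].get(base, 0) + 1
    return votes


def _consensus(votes: list[dict[str, int]]) -> str:
    out = []
    for tally in votes:
        total = sum(tally.values())
        if total < MIN_OVERHANG_SUPPORT:
            break
        ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            break  # tie: truncate the overhang here
        out.append(ranked[0][0])
    return "".join(out)


def extend_contig(seed: str, reads: list[FastqRecord],
                  cfg: Config, seed_id: str = "seed") -> ExtensionResult:
    """Extend ``seed`` from ``reads`` by end-overlap consensus voting.

    Both read orientations are considered. Deterministic given read order and
    config: voting has no randomness and ties truncate.
    """
    seed = seed.upper()
    if len(seed) < cfg.min_overlap_nt:
        raise ValueError("seed shorter than min_overlap_nt")
    pool: list[str] = []
    for r in reads:
        s = r.seq.upper()
        pool.append(s)
        pool.append(revcomp(s))
    contig = seed
    seed_offset = 0  # position of the original seed inside current contig
    cycles = 0
    blocks = 0
    changed_flags: list[bool] = []
    status = "max_blocks_reached"
    while blocks < cfg.max_blocks:
        block_start = contig
        for _ in range(cfg.cycles_per_block):
            cycles += 1
            right = _consensus(_end_votes(contig, seed, seed_offset, pool,
                                          cfg, "right"))
            left = _consensus(_end_votes(contig, seed, seed_offset, pool,
                                         cfg, "left"))
            if not right and not left:
                continue
            contig = left[::-1] + contig + right
            seed_offset += len(left)
        blocks += 1
        changed = contig != block_start
        changed_flags.append(changed)
        if not changed:
            status = "complete"
            break
    return ExtensionResult(seed_id, contig, cycles, blocks, status,
                           tuple(changed_flags))
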