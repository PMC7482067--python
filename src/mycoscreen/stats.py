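"""Survey statistics: prevalence, exact association, coinfection, agreement.

Prevalence tables count an isolate positive when either screening method
found a virus ("combined screening"); percentages render to one decimal with
half-up rounding, matching the survey's tables. The association between
developmental morphology and infection is tested with a two-sided Fisher
exact test in the minimum-likelihood convention: the p-value sums
hypergeometric point probabilities no larger than the observed table's.
TPM (transcripts per million) is the length-normalised abundance used as a
viral-titer proxy when comparing screening methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import hypergeom

from mycoscreen.census import CensusEntry
from mycoscreen.roster import TAXON_ORDER, HostIsolate

_RANKS = ("phylum", "subphylum", "order")


def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PrevalenceRow:
    taxon: str
    rank: str
    n: int
    positives: int
    pct: float  # one decimal, half-up

    def __post_init__(self):
        if not 0 <= self.positives <= self.n:
            raise ValueError("positives must lie in [0, n]")


@dataclass(frozen=True)
class Contingency2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.total < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def prevalence_table(roster: list[HostIsolate],
                     rank: str) -> list[PrevalenceRow]:
    """Per-taxon prevalence at a rank, plus a Total row (always last).

    Isolates without the requested rank are binned under "unranked". Rows
    follow the declared taxonomy order; undeclared labels sort after, by name.
    """
    if rank not in _RANKS:
        raise ValueError(f"rank must be one of {_RANKS}")
    bins: dict[str, list[HostIsolate]] = {}
    for host in roster:
        bins.setdefault(host.taxon_at(rank), []).append(host)

    def sort_key(taxon: str):
        if taxon == "unranked":
            return (2, taxon)
        return (0, TAXON_ORDER[taxon], "") if taxon in TAXON_ORDER \
            else (1, 0, taxon)

    rows = []
    for taxon in sorted(bins, key=sort_key):
        hosts = bins[taxon]
        pos = sum(h.combined_positive for h in hosts)
        rows.append(PrevalenceRow(taxon, rank, len(hosts), pos,
                                  round_half_up(100 * pos / len(hosts))))
    n_total = len(roster)
    pos_total = sum(h.combined_positive for h in roster)
    pct = round_half_up(100 * pos_total / n_total) if n_total else 0.0
    rows.append(PrevalenceRow("Total", rank, n_total, pos_total, pct))
    return rows


def fisher_exact(table: Contingency2x2) -> float:
    """Two-sided Fisher exact p-value (minimum-likelihood convention).

    With row margins fixed, the first cell follows a hypergeometric law; the
    p-value is the total probability of tables whose point probability does
    not exceed the observed table's (within a small relative tolerance for
    floating-point ties).
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.total
    r1, c1 = a + b, a + c
    rv = hypergeom(n, r1, c1)
    support = np.arange(max(0, c1 - (c + d)), min(r1, c1) + 1)
    pmf = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(1.0, max(p, float(p_obs)))


def coinfection_summary(
        census: list[CensusEntry] | list[int]) -> tuple[float, float]:
    """(mean, median) unique viruses per virus-positive sequenced host.

    Accepts census entries or raw per-host counts. Hosts with zero viruses
    are excluded; the mean reports one decimal (half-up) and the median is
    the midpoint of the sorted counts.
    """
    counts = [e.n_viruses if isinstance(e, CensusEntry) else int(e)
              for e in census]
    counts = sorted(c for c in counts if c > 0)
    if not counts:
        raise ValueError("census contains no virus-positive hosts")
    mean = round_half_up(sum(counts) / len(counts))
    mid = len(counts) // 2
    if len(counts) % 2:
        median = float(counts[mid])
    else:
        median = (counts[mid - 1] + counts[mid]) / 2
    return mean, median


def method_agreement(roster: list[HostIsolate]) -> float:
    """Percent concordance among isolates screened by both methods."""
    both = [h for h in roster
            if h.in_vitro_result != "not_done"
            and h.in_silico_result != "not_done"]
    if not both:
        raise ValueError("no isolates screened by both methods")
    concordant = sum(h.in_vitro_result == h.in_silico_result for h in both)
    return round_half_up(100 * concordant / len(both))


def tpm(counts, lengths) -> np.ndarray:
    """Transcripts per million from read counts and transcript lengths."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must have the same shape")
    if np.any(lengths <= 0):
        raise ValueError("transcript lengths must be positive")
    if not np.any(counts > 0):
        raise ValueError("all read counts are zero")
    rate = counts / lengths
    return 1e6 * rate / rate.sum()
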