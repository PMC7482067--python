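"""Packaged aggregate fixtures reconstructed from the survey's printed tables.

``table1_counts.tsv`` carries per-taxon sample sizes with positive counts
recovered from the printed one-decimal percentages (the reconstruction
round-trips exactly: re-rendering positives/n reproduces every printed
figure). ``morphology_counts.tsv`` holds the zoosporic morphology contingency
counts. The two files whose row-level detail the survey does not print —
the per-host coinfection distribution and the in vitro/in silico call pattern
behind the concordance figure — are labelled ``_synthetic`` and are
constrained only by the printed summaries (36 hosts / 85 viruses / median
1.5 / max 11; and 18 concordant + 2 + 1 discordant of 21).

Count rows expand into pseudo-rosters of :class:`HostIsolate` so the survey
statistics are recomputed by the same code paths as for real rosters.
"""

from __future__ import annotations

from pathlib import Path

from mycoscreen.io import read_tsv
from mycoscreen.roster import ORDERS, SUBPHYLA, HostIsolate
from mycoscreen.stats import Contingency2x2

DATA_DIR = Path(__file__).parent / "data"

_ORDER_TO_PHYLUM = {o: p for p, orders in ORDERS.items() for o in orders}
_SUBPHYLUM_TO_PHYLUM = {s: p for p, subs in SUBPHYLA.items() for s in subs}


def load_table1() -> list[dict]:
    header, rows = read_tsv(DATA_DIR / "table1_counts.tsv")
    return [dict(zip(header, row)) for row in rows]


def _isolate(i: int, phylum: str, subphylum: str, order: str,
             positive: bool, morphology: str = "unknown") -> HostIsolate:
    return HostIsolate(
        id=f"fix{i:04d}", phylum=phylum, subphylum=subphylum, order=order,
        morphology=morphology,
        in_silico_result="positive" if positive else "negative")


def table1_roster(rank: str) -> list[HostIsolate]:
    """Expand the Table-1 rows of one rank into a pseudo-roster.

    Each rank expands independently because the printed table mixes ranks
    (subphyla under two phyla, orders under two others) and its order-level
    sample sizes do not sum exactly to the phylum level.
    """
    roster: list[HostIsolate] = []
    i = 0
    for row in load_table1():
        if row["rank"] != rank:
            continue
        taxon, n, pos = row["taxon"], int(row["n"]), int(row["positives"])
        if rank == "phylum":
            phylum, subphylum, order = taxon, "", ""
        elif rank == "subphylum":
            phylum, subphylum, order = _SUBPHYLUM_TO_PHYLUM[taxon], taxon, ""
        else:
            phylum, subphylum, order = _ORDER_TO_PHYLUM[taxon], "", taxon
        for j in range(n):
            roster.append(_isolate(i, phylum, subphylum, order, j < pos))
            i += 1
    return roster


def total_roster() -> list[HostIsolate]:
    """Expand the printed survey-wide total (its own figure: the table's
    per-rank sample sizes do not sum exactly to it)."""
    row = next(r for r in load_table1() if r["rank"] == "total")
    n, pos = int(row["n"]), int(row["positives"])
    return [_isolate(i, "Mucoromycota", "", "", i < pos) for i in range(n)]


def morphology_roster() -> list[HostIsolate]:
    """Chytridiomycota isolates with known morphology, expanded from counts."""
    header, rows = read_tsv(DATA_DIR / "morphology_counts.tsv")
    roster: list[HostIsolate] = []
    i = 0
    for morphology, n, pos in ((r[0], int(r[1]), int(r[2])) for r in rows):
        for j in range(n):
            roster.append(_isolate(i, "Chytridiomycota", "", "", j < pos,
                                   morphology))
            i += 1
    return roster


def morphology_table() -> Contingency2x2:
    """2x2 polycentric/monocentric x positive/negative contingency table."""
    header, rows = read_tsv(DATA_DIR / "morphology_counts.tsv")
    by = {r[0]: (int(r[1]), int(r[2])) for r in rows}
    (pn, pp), (mn, mp) = by["polycentric"], by["monocentric"]
    return Contingency2x2(pp, pn - pp, mp, mn - mp)


def agreement_roster() -> list[HostIsolate]:
    header, rows = read_tsv(DATA_DIR / "agreement_synthetic.tsv")
    return [HostIsolate(id=r[0], phylum="Mucoromycota",
                        in_vitro_result=r[1], in_silico_result=r[2])
            for r in rows]


def coinfection_counts() -> list[int]:
    header, rows = read_tsv(DATA_DIR / "coinfection_synthetic.tsv")
    return [int(r[1]) for r in rows]
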