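"""Host roster: one record per fungal culture screened for viruses.

The roster is the unit of prevalence counting. Each isolate carries its
taxonomy (phylum, optionally subphylum and order, drawn from the survey's
controlled vocabulary), its developmental morphology for the zoosporic
association test, the two screening results (in vitro dsRNA chromatography
and in silico transcriptome mining; ``not_done`` when a method was not
applied), and which genome is available for the endogeny check.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from mycoscreen.io import read_tsv, write_tsv

PHYLA = ("Mucoromycota", "Zoopagomycota", "Blastocladiomycota",
         "Chytridiomycota", "Neocallimastigomycota", "Cryptomycota")

SUBPHYLA = {
    "Mucoromycota": ("Glomeromycotina", "Mucoromycotina", "Mortierellomycotina"),
    "Zoopagomycota": ("Entomophthoromycotina", "Kickxellomycotina",
                      "Zoopagomycotina"),
}

ORDERS = {
    "Blastocladiomycota": ("Blastocladiales", "Physodermatales"),
    "Chytridiomycota": ("Monoblepharidales", "Cladochytriales", "Synchytriales",
                        "Chytridiales", "Lobulomycetales", "Rhizophydiales",
                        "Rhizophlyctidales", "Spizellomycetales"),
}

MORPHOLOGIES = ("monocentric", "polycentric", "unknown")
RESULTS = ("positive", "negative", "not_done")
GENOME_AVAILABILITY = ("own", "relative", "none")

#: Declared presentation order of taxa, used to sort prevalence rows.
TAXON_ORDER: dict[str, int] = {}
for _p in PHYLA:
    TAXON_ORDER[_p] = len(TAXON_ORDER)
    for _s in SUBPHYLA.get(_p, ()):
        TAXON_ORDER[_s] = len(TAXON_ORDER)
    for _o in ORDERS.get(_p, ()):
        TAXON_ORDER[_o] = len(TAXON_ORDER)


@dataclass(frozen=True)
class HostIsolate:
    id: str
    phylum: str
    subphylum: str = ""   # empty when the rank is not assigned
    order: str = ""
    morphology: str = "unknown"
    in_vitro_result: str = "not_done"
    in_silico_result: str = "not_done"
    genome_available: str = "none"

    def __post_init__(self):
        if self.phylum not in PHYLA:
            raise ValueError(f"unknown phylum {self.phylum!r}")
        if self.subphylum and self.subphylum not in SUBPHYLA.get(self.phylum, ()):
            raise ValueError(
                f"subphylum {self.subphylum!r} not declared for {self.phylum}")
        if self.order and self.order not in ORDERS.get(self.phylum, ()):
            raise ValueError(
                f"order {self.order!r} not declared for {self.phylum}")
        if self.morphology not in MORPHOLOGIES:
            raise ValueError(f"unknown morphology {self.morphology!r}")
        for res in (self.in_vitro_result, self.in_silico_result):
            if res not in RESULTS:
                raise ValueError(f"unknown screening result {res!r}")
        if self.genome_available not in GENOME_AVAILABILITY:
            raise ValueError(
                f"unknown genome availability {self.genome_available!r}")

    def taxon_at(self, rank: str) -> str:
        value = {"phylum": self.phylum, "subphylum": self.subphylum,
                 "order": self.order}[rank]
        return value or "unranked"

    @property
    def combined_positive(self) -> bool:
        """Positive by either screening method (combined screening)."""
        return "positive" in (self.in_vitro_result, self.in_silico_result)


_COLUMNS = ["id", "phylum", "subphylum", "order", "morphology",
            "in_vitro_result", "in_silico_result", "genome_available"]


def write_roster(path: str | Path, roster: list[HostIsolate]) -> None:
    write_tsv(path, _COLUMNS,
              ([getattr(h, c) for c in _COLUMNS] for h in roster))


def read_roster(path: str | Path) -> list[HostIsolate]:
    header, rows = read_tsv(path)
    if header != _COLUMNS:
        raise ValueError(f"{path}: expected roster columns {_COLUMNS}")
    roster = [HostIsolate(**dict(zip(header, row))) for row in rows]
    ids = [h.id for h in roster]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"{path}: duplicate isolate ids {dupes}")
    return roster
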