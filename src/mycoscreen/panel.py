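"""Reference panel I/O: labelled proteins and aligned RdRp-like families.

The panel plays the role of the public protein databases in the original
survey: each reference protein carries a Riboviria branch label (1-5 or
unassigned), an ``is_viral`` flag (the stand-in for a taxonomy lookup) and an
``is_mitovirus`` flag that triggers mitochondrial-code retranslation.
References live in a FASTA file with structured headers::

    >ref001 branch=4 is_viral=1 is_mitovirus=0

Families are aligned FASTA files, one per family, used to build profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from mycoscreen.io import read_fasta, write_fasta

BRANCHES = ("1", "2", "3", "4", "5", "unassigned")


@dataclass(frozen=True)
class PanelRef:
    id: str
    protein: str
    branch: str        # one of BRANCHES
    is_viral: bool
    is_mitovirus: bool

    def __post_init__(self):
        if self.branch not in BRANCHES:
            raise ValueError(f"unknown branch label {self.branch!r}")


def write_panel(path: str | Path, refs: list[PanelRef]) -> None:
    records = []
    for r in refs:
        header = (f"{r.id} branch={r.branch} is_viral={int(r.is_viral)} "
                  f"is_mitovirus={int(r.is_mitovirus)}")
        records.append((header, r.protein))
    write_fasta(path, records)


def read_panel(path: str | Path) -> list[PanelRef]:
    refs = []
    for header, seq in read_fasta(path, alphabet="protein"):
        fields = header.split()
        rid = fields[0]
        tags = dict(f.split("=", 1) for f in fields[1:] if "=" in f)
        refs.append(PanelRef(
            id=rid,
            protein=seq,
            branch=tags.get("branch", "unassigned"),
            is_viral=tags.get("is_viral", "0") == "1",
            is_mitovirus=tags.get("is_mitovirus", "0") == "1",
        ))
    return refs
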