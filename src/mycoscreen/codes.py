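"""Genetic codes for ORF translation.

Two codes matter for this pipeline: the standard (universal) nuclear code and
a mold-mitochondrial code under which TGA encodes tryptophan. Mitoviruses
replicate in mitochondria, so their RdRp ORF is intact only under the
mitochondrial code — under the standard code the TGA-tryptophan codons read as
internal stops and the ORF fragments. Tables are taken from the NCBI
translation tables (1 and 4) as shipped with Biopython; other NCBI table ids
can be loaded for organisms where the mitochondrial variant differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from Bio.Data import CodonTable

STOP = "*"


@dataclass(frozen=True)
class GeneticCode:
    id: str
    table: dict[str, str] = field(repr=False)  # 64 codons -> aa or '*'
    stops: frozenset[str] = field(repr=False)

    @classmethod
    def from_ncbi(cls, code_id: str, ncbi_id: int) -> "GeneticCode":
        ncbi = CodonTable.unambiguous_dna_by_id[ncbi_id]
        table = {}
        for codon in ("".join(c) for c in product("TCAG", repeat=3)):
            table[codon] = ncbi.forward_table.get(codon, STOP)
        stops = frozenset(ncbi.stop_codons)
        assert len(table) == 64 and all(table[c] == STOP for c in stops)
        return cls(code_id, table, stops)

    def codons_for(self, aa: str) -> list[str]:
        """Synonymous codons for an amino acid, sorted for determinism."""
        return sorted(c for c, a in self.table.items() if a == aa)

    def translate_codon(self, codon: str) -> str:
        codon = codon.upper().replace("U", "T")
        if codon in self.table:
            return self.table[codon]
        if set(codon) <= set("ACGTN"):
            return "X"
        raise ValueError(f"illegal codon {codon!r}")


STANDARD = GeneticCode.from_ncbi("standard", 1)
#: Mold/protozoan mitochondrial table (NCBI 4): TGA -> Trp, AGA/AGG unchanged.
MITO = GeneticCode.from_ncbi("mito", 4)

CODES = {"standard": STANDARD, "mito": MITO}
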