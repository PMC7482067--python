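"""Six-frame ORF prediction and translation under selectable genetic codes.

ORFs are stop-to-stop (not ATG-anchored), matching viral-genomics practice:
assembled viral contigs are frequently 5'-truncated and the RdRp reading frame
need not begin with the initiator in the assembly. ORFs with no upstream stop
are reported and flagged 5'-partial. Coordinates are 0-based half-open on the
forward strand of the contig throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

from mycoscreen.codes import CODES, STOP, GeneticCode

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMP)[::-1]


@dataclass(frozen=True)
class Orf:
    contig_id: str
    strand: str           # '+' or '-'
    frame: int            # 0..2 offset on the translated strand
    start: int            # 0-based half-open, forward strand of contig
    end: int
    protein: str          # no trailing stop symbol
    code_id: str
    partial5: bool        # no upstream in-frame stop observed

    @property
    def length_aa(self) -> int:
        return len(self.protein)


def translate(nt: str, code: GeneticCode) -> str:
    """Translate a DNA string whose length is divisible by 3.

    N-containing codons translate to ``X``; stops render as ``*``.
    """
    nt = nt.upper()
    if len(nt) % 3:
        raise ValueError(f"sequence length {len(nt)} not divisible by 3")
    return "".join(code.translate_codon(nt[i:i + 3]) for i in range(0, len(nt), 3))


def _frame_orfs(contig_id: str, seq: str, strand: str, frame: int,
                min_aa: int, code: GeneticCode, contig_len: int) -> list[Orf]:
    usable = (len(seq) - frame) // 3 * 3
    if usable <= 0:
        return []
    aa = translate(seq[frame:frame + usable], code)
    orfs = []
    start_aa = 0
    for i, ch in enumerate(aa + STOP):
        if ch != STOP and i < len(aa):
            continue
        # segment [start_aa, i) is stop-free
        if i - start_aa >= min_aa:
            has_stop = i < len(aa)  # a real stop codon terminates the segment
            nt_start = frame + 3 * start_aa
            nt_end = frame + 3 * i + (3 if has_stop else 0)
            if strand == "+":
                s, e = nt_start, nt_end
            else:
                s, e = contig_len - nt_end, contig_len - nt_start
            orfs.append(Orf(contig_id, strand, frame, s, e,
                            aa[start_aa:i], code.id, partial5=start_aa == 0))
        start_aa = i + 1
    return orfs


def find_orfs(contig: str, min_aa: int, code: GeneticCode | str,
              contig_id: str = "") -> list[Orf]:
    """All stop-to-stop ORFs of >= ``min_aa`` residues on both strands.

    Sorted by descending protein length, then by (strand, frame, start) for
    determinism. The trailing stop codon, when present, is included in the
    nucleotide span but not in the protein.
    """
    if isinstance(code, str):
        code = CODES[code]
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    contig = contig.upper()
    out: list[Orf] = []
    for strand, seq in (("+", contig), ("-", revcomp(contig))):
        for frame in range(3):
            out.extend(_frame_orfs(contig_id, seq, strand, frame,
                                   min_aa, code, len(contig)))
    out.sort(key=lambda o: (-len(o.protein), o.strand, o.frame, o.start))
    return out
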