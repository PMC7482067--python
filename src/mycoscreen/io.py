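"""FASTA / FASTQ / TSV plumbing shared by every pipeline stage.

The parsers are deliberately strict line-level readers: malformed records are
reported with the offending line number, ids must be unique within a file, and
the residue alphabet is validated (DNA, protein, or gapped protein for aligned
families). Sanger phred+33 is the only FASTQ quality encoding accepted.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, NamedTuple

DNA_CHARS = set("ACGTN")
PROTEIN_CHARS = set("ACDEFGHIKLMNPQRSTVWYX*")
GAP_CHARS = set("-.")


class FastaParseError(ValueError):
    pass


class FastqRecord(NamedTuple):
    id: str
    seq: str
    qual: str  # phred+33 string, same length as seq

    def phred(self) -> list[int]:
        return [ord(c) - 33 for c in self.qual]


def _check_alphabet(seq: str, alphabet: str, path, lineno: int) -> None:
    if alphabet == "any":
        return
    allowed = {
        "dna": DNA_CHARS,
        "protein": PROTEIN_CHARS,
        "aligned": PROTEIN_CHARS | GAP_CHARS,
    }[alphabet]
    bad = set(seq.upper()) - allowed
    if bad:
        raise FastaParseError(
            f"{path}:{lineno}: illegal character(s) {sorted(bad)} "
            f"for alphabet {alphabet!r}")


def read_fasta(path: str | Path, alphabet: str = "any") -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` preserving order.

    ``alphabet`` is one of ``dna``, ``protein``, ``aligned`` (gapped protein)
    or ``any``. Gap characters are legal only in ``aligned`` mode. The record
    id is the header token before the first whitespace; ids must be unique.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    current: str | None = None
    chunks: list[str] = []
    start_line = 0

    def flush(lineno: int) -> None:
        nonlocal current, chunks
        if current is None:
            return
        seq = "".join(chunks)
        _check_alphabet(seq, alphabet, path, start_line)
        records.append((current, seq))
        current, chunks = None, []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(lineno)
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path}:{lineno}: empty FASTA header")
                rid = header.split()[0]
                if rid in seen:
                    raise FastaParseError(
                        f"{path}:{lineno}: duplicate record id {rid!r}")
                seen.add(rid)
                current = header
                start_line = lineno
            else:
                if current is None:
                    raise FastaParseError(
                        f"{path}:{lineno}: sequence data before first header")
                chunks.append(line.strip())
        flush(lineno if records or current else 0)
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]],
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            if seq:
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")
            else:
                fh.write("\n")


def read_fastq(path: str | Path) -> list[FastqRecord]:
    path = Path(path)
    out: list[FastqRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) % 4:
        raise FastaParseError(f"{path}: truncated FASTQ (lines not multiple of 4)")
    for i in range(0, len(lines), 4):
        lineno = i + 1
        if not lines[i].startswith("@"):
            raise FastaParseError(f"{path}:{lineno}: expected '@' header")
        rid = lines[i][1:].split()[0]
        seq, plus, qual = lines[i + 1], lines[i + 2], lines[i + 3]
        if not plus.startswith("+"):
            raise FastaParseError(f"{path}:{lineno + 2}: expected '+' separator")
        if len(qual) != len(seq):
            raise FastaParseError(
                f"{path}:{lineno + 3}: quality length {len(qual)} != "
                f"sequence length {len(seq)}")
        out.append(FastqRecord(rid, seq, qual))
    return out


def write_fastq(path: str | Path, records: Iterable[FastqRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")


def write_tsv(path: str | Path, header: list[str],
              rows: Iterable[Iterable[object]]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_tsv(path: str | Path) -> tuple[list[str], list[list[str]]]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        return [], []
    header = lines[0].split("\t")
    return header, [line.split("\t") for line in lines[1:] if line]
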