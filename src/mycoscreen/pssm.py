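"""Position-specific scoring profiles for RdRp domain detection.

A profile is built from an aligned protein family: alignment columns with at
most 50% gaps become match columns, and each match column carries 20 log-odds
scores in bits,

    score(col, aa) = log2( ((count + pc * bg_aa) / (n_col + pc)) / bg_aa )

with ``count`` the residue count in the column, ``n_col`` the non-gap count,
``pc`` a pseudocount mass distributed by the background, and ``bg`` the
Robinson-Robinson background frequencies used with BLOSUM62. Scanning is a
Smith-Waterman-style local alignment of a translated ORF against the profile
columns with affine gap penalties in bits. The fraction of profile columns
spanned by the best hit is the "domain coverage" that the census criteria
consume, and the span's position against the profile ends assigns the
N-terminal / C-terminal fragment class used by the concatenation rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from mycoscreen.align import align_local
from mycoscreen.orfs import Orf

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

# Robinson & Robinson (1991) amino-acid frequencies, the BLOSUM62 background.
_RR = {
    "A": 0.078047, "R": 0.051291, "N": 0.044873, "D": 0.053640,
    "C": 0.019246, "Q": 0.042644, "E": 0.062949, "G": 0.073772,
    "H": 0.021992, "I": 0.051420, "L": 0.090191, "K": 0.057438,
    "M": 0.022425, "F": 0.038556, "P": 0.052028, "S": 0.071198,
    "T": 0.058413, "W": 0.013298, "Y": 0.032165, "V": 0.064409,
}
BLOSUM62_BACKGROUND = np.array([_RR[a] for a in AA_ORDER])
BLOSUM62_BACKGROUND /= BLOSUM62_BACKGROUND.sum()

#: Fraction of profile ends a hit must reach to be called complete on a side.
TERMINUS_SLACK = 0.05


@dataclass(frozen=True)
class Profile:
    name: str
    scores: np.ndarray      # (ncols, 20) log-odds in bits
    consensus: str          # per-column argmax residue
    background: np.ndarray  # (20,) frequencies, sums to 1

    @property
    def ncols(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class ProfileHit:
    orf: Orf | None
    profile_name: str
    bit_score: float
    c_start: int   # profile column span, 0-based half-open
    c_end: int
    q_start: int   # span on the query protein
    q_end: int
    coverage: float
    terminus_class: str  # complete | n_term | c_term | internal


def build_profile(alignment: list[tuple[str, str]],
                  background: np.ndarray | None = None,
                  pseudocount: float = 1.0,
                  name: str = "profile") -> Profile:
    """Build a log-odds profile from gapped protein records.

    Columns whose gap fraction exceeds 0.5 are dropped; exactly 0.5 is kept.
    """
    if len(alignment) < 2:
        raise ValueError("profile needs >= 2 aligned sequences")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    width = len(alignment[0][1])
    if any(len(seq) != width for _, seq in alignment):
        raise ValueError("ragged alignment: sequences differ in gapped length")
    bg = BLOSUM62_BACKGROUND if background is None else np.asarray(background, float)
    bg = bg / bg.sum()
    nseq = len(alignment)
    cols = []
    for j in range(width):
        residues = [seq[j].upper() for _, seq in alignment]
        gaps = sum(r in "-." for r in residues)
        if gaps / nseq > 0.5:
            continue
        counts = np.zeros(20)
        for r in residues:
            if r in AA_INDEX:
                counts[AA_INDEX[r]] += 1
        n_col = counts.sum()
        if n_col == 0:
            continue  # column of gaps/ambiguity only
        freqs = (counts + pseudocount * bg) / (n_col + pseudocount)
        cols.append(np.log2(freqs / bg))
    if not cols:
        raise ValueError("alignment has no usable match columns")
    scores = np.vstack(cols)
    consensus = "".join(AA_ORDER[int(j)] for j in scores.argmax(axis=1))
    return Profile(name, scores, consensus, bg)


def _terminus_class(c_start: int, c_end: int, ncols: int) -> str:
    slack = TERMINUS_SLACK * ncols
    start_side = c_start <= slack
    end_side = (ncols - c_end) <= slack
    if start_side and end_side:
        return "complete"
    if start_side:
        return "n_term"
    if end_side:
        return "c_term"
    return "internal"


def scan(protein: str, profile: Profile, gap_open: float = 4.0,
         gap_extend: float = 1.0, min_bits: float = 20.0,
         orf: Orf | None = None) -> ProfileHit | None:
    """Best local hit of ``protein`` against ``profile``, or None below gate.

    Residues outside the 20-letter alphabet (X, ambiguity) score 0 against
    every column.
    """
    if not protein:
        raise ValueError("empty protein")
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    idx = np.array([AA_INDEX.get(a, -1) for a in protein.upper()])
    S = np.zeros((len(protein), profile.ncols))
    known = idx >= 0
    S[known, :] = profile.scores[:, idx[known]].T
    aln = align_local(S, gap_open, gap_extend)
    if aln.score < min_bits or aln.t_end == aln.t_start:
        return None
    coverage = (aln.t_end - aln.t_start) / profile.ncols
    return ProfileHit(
        orf=orf,
        profile_name=profile.name,
        bit_score=aln.score,
        c_start=aln.t_start,
        c_end=aln.t_end,
        q_start=aln.q_start,
        q_end=aln.q_end,
        coverage=coverage,
        terminus_class=_terminus_class(aln.t_start, aln.t_end, profile.ncols),
    )


def profile_to_tsv(profile: Profile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# name=%s\n" % profile.name)
        fh.write("# background=%s\n" % ",".join(
            "%.6f" % x for x in profile.background))
        fh.write("col\tconsensus\t" + "\t".join(AA_ORDER) + "\n")
        for j in range(profile.ncols):
            fh.write("%d\t%s\t%s\n" % (
                j, profile.consensus[j],
                "\t".join("%.5f" % s for s in profile.scores[j])))


def profile_from_tsv(path: str | Path) -> Profile:
    name = "profile"
    background = BLOSUM62_BACKGROUND
    rows = []
    consensus = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("# name="):
            name = line.split("=", 1)[1]
        elif line.startswith("# background="):
            background = np.array(
                [float(x) for x in line.split("=", 1)[1].split(",")])
        elif line and not line.startswith(("#", "col\t")):
            parts = line.split("\t")
            consensus.append(parts[1])
            rows.append([float(x) for x in parts[2:]])
    return Profile(name, np.array(rows), "".join(consensus), background)
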