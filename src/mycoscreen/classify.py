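"""Confirmation of profile hits against the labelled reference panel.

A profile hit alone says "RdRp-like"; the classifier re-creates the survey's
BLAST confirmation step: the ORF protein is aligned (Smith-Waterman, BLOSUM62,
gap costs 11/1) against every panel reference, the best-scoring reference is
taken, a Karlin-Altschul E-value E = k*m*n*exp(-lambda*score) is computed over
the whole panel as search space, and the hit is confirmed only if the best
reference is viral and E falls below the configured threshold (1e-10). The
best hit's branch label classifies the virus; its mitovirus flag triggers
mitochondrial-code retranslation upstream in the pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from mycoscreen.align import align_local
from mycoscreen.config import Config
from mycoscreen.orfs import Orf
from mycoscreen.panel import PanelRef
from mycoscreen.pssm import AA_INDEX, AA_ORDER, ProfileHit

#: 21x21 scoring matrix: BLOSUM62 over the 20 standard residues, index 20 is
#: the catch-all for X/ambiguity and scores 0 against everything.
_B62 = substitution_matrices.load("BLOSUM62")
SUBMAT = np.zeros((21, 21))
for _i, _a in enumerate(AA_ORDER):
    for _j, _b in enumerate(AA_ORDER):
        SUBMAT[_i, _j] = _B62[_a, _b]


@dataclass(frozen=True)
class ReferenceHit:
    orf: Orf | None
    reference_id: str
    score: float           # raw Smith-Waterman score
    bit_score: float       # lambda*S - ln k, in bits
    evalue: float
    identity: float        # matches / alignment columns (gaps included)
    branch: str
    is_viral: bool
    is_mitovirus: bool


def _indices(protein: str) -> np.ndarray:
    return np.array([AA_INDEX.get(a, 20) for a in protein.upper()])


def local_align(a: str, b: str, matrix: np.ndarray = SUBMAT,
                gap_open: float = 11.0, gap_extend: float = 1.0):
    """Optimal local alignment of two proteins.

    Returns ``(score, identity, (a_span, b_span))`` where identity is matches
    over all alignment columns including gap columns. Unknown residues score 0
    against every partner.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    ai, bi = _indices(a), _indices(b)
    S = matrix[np.ix_(ai, bi)]
    aln = align_local(S, gap_open, gap_extend)
    if not aln.ops:
        return 0.0, 0.0, ((0, 0), (0, 0))
    matches = sum(1 for op, i, j in aln.ops
                  if op == "M" and a[i].upper() == b[j].upper())
    identity = matches / len(aln.ops)
    return aln.score, identity, ((aln.q_start, aln.q_end),
                                 (aln.t_start, aln.t_end))


def evalue(score: float, m: int, n: int, lam: float = 0.267,
           k: float = 0.041) -> float:
    """Karlin-Altschul expected number of chance hits at this score.

    ``m`` is the query length, ``n`` the total search-space (panel) length.
    """
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    if lam <= 0 or k <= 0:
        raise ValueError("Karlin-Altschul parameters must be positive")
    return k * m * n * math.exp(-lam * score)


def classify(profile_hit: ProfileHit, panel: list[PanelRef],
             cfg: Config) -> ReferenceHit | None:
    """Best confirmed panel hit for a profile-positive ORF, or None.

    The best reference is chosen by raw alignment score with ties broken by
    reference id (lexicographic), which makes the result invariant to panel
    order. None is returned when the best reference is non-viral or its
    E-value misses the gate; the caller then reports the ORF as an
    unconfirmed candidate.
    """
    if not panel:
        raise ValueError("empty reference panel")
    query = profile_hit.orf.protein if profile_hit.orf else None
    if not query:
        raise ValueError("profile hit carries no ORF protein")
    n_total = sum(len(r.protein) for r in panel)
    best: tuple[float, str] | None = None
    best_ref = None
    best_identity = 0.0
    for ref in sorted(panel, key=lambda r: r.id):
        score, identity, _ = local_align(query, ref.protein)
        key = (-score, ref.id)
        if best is None or key < best:
            best = key
            best_ref = ref
            best_identity = identity
    assert best_ref is not None
    score = -best[0]
    e = evalue(score, len(query), n_total, cfg.ka_lambda, cfg.ka_k)
    if not best_ref.is_viral or e >= cfg.evalue_threshold:
        return None
    bits = (cfg.ka_lambda * score - math.log(cfg.ka_k)) / math.log(2)
    return ReferenceHit(
        orf=profile_hit.orf,
        reference_id=best_ref.id,
        score=score,
        bit_score=bits,
        evalue=e,
        identity=best_identity,
        branch=best_ref.branch,
        is_viral=best_ref.is_viral,
        is_mitovirus=best_ref.is_mitovirus,
    )
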