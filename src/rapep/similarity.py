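"""Short-peptide similarity search with top-hit label transfer.

Queries are aligned against every sequence of a labelled reference set with
full Smith-Waterman local alignment under short-peptide scoring defaults
(PAM30, gap open 9 / extend 1). Scores are converted to e-values with the
standard Karlin-Altschul form ``E = K * m * n * exp(-lambda * S)``, where
``m`` is the query length and ``n`` the total residue count of the
reference database; ``lambda`` is solved for the configured matrix under
ungapped statistics and ``K`` is a shipped constant. The query inherits
the label of its best hit when that hit's e-value passes the cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

from .datasets import AMINO_ACIDS, Peptide, PeptideDataset

# Robinson-Robinson background residue frequencies.
_BACKGROUND = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

_KARLIN_K = 0.13  # shipped constant for the ungapped approximation

NO_HIT = "no_hit"


@dataclass(frozen=True)
class AlignmentHit:
    query_id: str
    subject_id: str
    score: float
    evalue: float
    subject_label: str


@lru_cache(maxsize=None)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    # BLAST-style affine cost: a gap of length k costs open + k * extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


@lru_cache(maxsize=None)
def karlin_lambda(matrix_name: str = "PAM30") -> float:
    """Ungapped Karlin-Altschul lambda for a substitution matrix: the root
    of ``sum_ij p_i p_j exp(lambda * s_ij) = 1``."""
    matrix = substitution_matrices.load(matrix_name)
    p = np.array([_BACKGROUND[a] for a in AMINO_ACIDS])
    s = np.array([[matrix[a, b] for b in AMINO_ACIDS] for a in AMINO_ACIDS])

    def f(lam: float) -> float:
        return float(p @ np.exp(lam * s) @ p - 1.0)

    return float(brentq(f, 1e-4, 2.0))


def local_align(a: str, b: str, matrix_name: str = "PAM30",
                gap_open: int = 9, gap_extend: int = 1) -> float:
    """Optimal Smith-Waterman local alignment score (0 when nothing
    positive-scoring aligns)."""
    if not a or not b:
        return 0.0
    score = _aligner(matrix_name, gap_open, gap_extend).score(a, b)
    return float(max(score, 0.0))


def evalue_from_score(score: float, query_len: int, db_residues: int,
                      matrix_name: str = "PAM30") -> float:
    lam = karlin_lambda(matrix_name)
    return float(_KARLIN_K * query_len * db_residues * np.exp(-lam * score))


def _identity(a: str, b: str, matrix_name: str, gap_open: int, gap_extend: int) -> float:
    aln = _aligner(matrix_name, gap_open, gap_extend).align(a, b)
    if len(aln) == 0:
        return 0.0
    best = aln[0]
    ident = sum(
        1
        for (s1, e1), (s2, e2) in zip(best.aligned[0], best.aligned[1])
        for i, j in zip(range(s1, e1), range(s2, e2))
        if a[i] == b[j]
    )
    length = sum(e - s for s, e in best.aligned[0])
    return ident / length if length else 0.0


def search_hits(query, reference: PeptideDataset, matrix_name: str = "PAM30",
                gap_open: int = 9, gap_extend: int = 1) -> list[AlignmentHit]:
    """Align the query against every labelled reference sequence; hits
    sorted by score (descending), ties by identity then subject id."""
    if len(reference) == 0:
        raise ValueError("empty reference dataset")
    qseq = query.sequence if isinstance(query, Peptide) else str(query)
    qid = query.id if isinstance(query, Peptide) else "query"
    db_residues = sum(len(p) for p in reference)
    hits = []
    for subj in reference:
        score = local_align(qseq, subj.sequence, matrix_name, gap_open, gap_extend)
        hits.append(
            AlignmentHit(
                query_id=qid,
                subject_id=subj.id,
                score=score,
                evalue=evalue_from_score(score, len(qseq), db_residues, matrix_name),
                subject_label=subj.label,
            )
        )
    best = max(h.score for h in hits)
    keyed = []
    for h in hits:
        ident = (
            _identity(qseq, next(p.sequence for p in reference if p.id == h.subject_id),
                      matrix_name, gap_open, gap_extend)
            if h.score == best and h.score > 0
            else 0.0
        )
        keyed.append(((-h.score, -ident, h.subject_id), h))
    keyed.sort(key=lambda t: t[0])
    return [h for _, h in keyed]


def top_hit_label(query, reference: PeptideDataset, evalue_cutoff: float = 10.0,
                  matrix_name: str = "PAM30", gap_open: int = 9,
                  gap_extend: int = 1) -> tuple[str, AlignmentHit | None]:
    """Label of the best-scoring reference hit with e-value <= cutoff.

    Returns ``(label, hit)`` where label is ``positive`` / ``negative`` /
    ``no_hit`` (hit is ``None`` in the latter case).
    """
    hits = search_hits(query, reference, matrix_name, gap_open, gap_extend)
    best = hits[0]
    if best.score <= 0 or best.evalue > evalue_cutoff:
        return NO_HIT, None
    return best.subject_label, best


def write_hit_table(hits, path) -> None:
    with open(path, "w") as fh:
        fh.write("query\tsubject\tscore\tevalue\tlabel\n")
        for h in hits:
            fh.write(f"{h.query_id}\t{h.subject_id}\t{h.score:g}\t{h.evalue:.3g}\t{h.subject_label}\n")
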