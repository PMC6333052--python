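"""Local pairwise alignment with Karlin-Altschul statistics.

The engine computes optimal Smith-Waterman local alignment scores under
affine gap penalties and a substitution matrix (BLOSUM62 by default, with X
scoring 0 against everything), then converts raw scores into bit scores

    bits = (lambda * raw - ln K) / ln 2

and e-values E = m * n * 2^(-bits) with a per-pair search space m*n.  The
dynamic programming itself runs through Biopython's C ``PairwiseAligner``;
the statistics are computed here.  A gap of length L costs
``gap_open + L * gap_extend`` (NCBI convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

#: Default gapped Karlin-Altschul parameters for BLOSUM62 with gap costs 11/1.
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


def blosum62_with_neutral_x() -> substitution_matrices.Array:
    """BLOSUM62 with the X row/column zeroed (X scores 0 vs everything)."""
    m = substitution_matrices.load("BLOSUM62").copy()
    for ch in m.alphabet:
        m["X", ch] = 0.0
        m[ch, "X"] = 0.0
    return m


@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap costs and Karlin-Altschul parameters."""

    matrix: substitution_matrices.Array = field(default_factory=blosum62_with_neutral_x)
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = DEFAULT_LAMBDA
    k_const: float = DEFAULT_K

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.gap_extend > self.gap_open:
            raise ValueError("gap_extend must not exceed gap_open")
        if self.lambda_ <= 0 or self.k_const <= 0:
            raise ValueError("lambda and K must be positive")
        arr = np.asarray(self.matrix)
        if not np.allclose(arr, arr.T):
            raise ValueError("substitution matrix must be symmetric")
        self._aligner: Optional[Align.PairwiseAligner] = None

    @property
    def aligner(self) -> Align.PairwiseAligner:
        """A cached Biopython local aligner configured for this scheme."""
        if self._aligner is None:
            a = Align.PairwiseAligner()
            a.mode = "local"
            a.substitution_matrix = self.matrix
            # Biopython charges open_gap_score for the first gap residue:
            # NCBI-style open+extend for the first, extend thereafter.
            a.open_gap_score = -(self.gap_open + self.gap_extend)
            a.extend_gap_score = -self.gap_extend
            self._aligner = a
        return self._aligner

    def bit_score(self, raw_score: float) -> float:
        return (self.lambda_ * raw_score - math.log(self.k_const)) / math.log(2)


def evalue(bit_score: float, m: int, n: int) -> float:
    """Expected number of chance hits at >= bit_score in an m x n search space."""
    if m < 1 or n < 1:
        raise ValueError("search space dimensions must be >= 1")
    return float(m) * float(n) * 2.0 ** (-bit_score)


@dataclass(frozen=True)
class AlignmentHit:
    """One local-alignment result with raw score, bit score and e-value."""

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float


def local_align(a, b, scheme: ScoringScheme | None = None) -> AlignmentHit:
    """Optimal Smith-Waterman local alignment of two protein sequences.

    Sequences may be :class:`~madsbox.seqio.ProteinSequence` objects or plain
    strings.  The empty local alignment scores 0, so ``raw_score >= 0``.
    """
    if scheme is None:
        scheme = ScoringScheme()
    sa = getattr(a, "residues", a)
    sb = getattr(b, "residues", b)
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    alphabet = set(scheme.matrix.alphabet)
    bad = (set(sa) | set(sb)) - alphabet
    if bad:
        raise ValueError(f"residues absent from substitution matrix: {sorted(bad)}")
    try:
        raw = scheme.aligner.score(sa, sb)
    except ValueError:
        # no positive-scoring local alignment exists
        raw = 0.0
    raw = max(0, int(round(raw)))
    bits = scheme.bit_score(raw)
    return AlignmentHit(
        query_id=getattr(a, "id", "query"),
        subject_id=getattr(b, "id", "subject"),
        raw_score=raw,
        bit_score=bits,
        evalue=evalue(bits, len(sa), len(sb)),
    )


def search_database(
    query,
    db: Sequence,
    scheme: ScoringScheme | None = None,
    exclude_ids: Iterable[str] = (),
) -> list[AlignmentHit]:
    """Align a query against every non-excluded subject in a database.

    Returns one hit per subject, ordered by descending bit score with ties
    broken by subject id.
    """
    if scheme is None:
        scheme = ScoringScheme()
    excluded = set(exclude_ids)
    hits = [
        local_align(query, subject, scheme)
        for subject in db
        if getattr(subject, "id", None) not in excluded
    ]
    hits.sort(key=lambda h: (-h.bit_score, h.subject_id))
    return hits


def write_hits_tsv(hits: Iterable[AlignmentHit], path) -> None:
    """Tabular hit output: query, subject, raw score, bit score, e-value."""
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("query_id\tsubject_id\traw_score\tbit_score\tevalue\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.raw_score}\t"
                f"{h.bit_score:.4f}\t{h.evalue:.6g}\n"
            )
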