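"""Pairwise-distance conservation summaries per domain.

Uncorrected p-distance (proportion of differing comparable columns) with
pairwise deletion of gap/X columns, summarized per region as mean and
variance over all unordered sequence pairs with a column-bootstrap standard
error.  Higher mean distance means higher sequence diversity; relating the
per-region diversity ranking to per-region model accuracy quantifies how
domain variability drives discriminability.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import ScoringScheme
from .domain_scan import RegionTag

_SKIP = {"-", "X", "."}


def p_distance(a: str, b: str) -> float:
    """Proportion of comparable aligned columns at which two rows differ.

    Rows must be pre-aligned (equal length); columns containing a gap or X in
    either row are skipped pairwise.  Zero comparable columns is an error.
    """
    a = getattr(a, "residues", a)
    b = getattr(b, "residues", b)
    if len(a) != len(b):
        raise ValueError(f"aligned rows differ in length: {len(a)} vs {len(b)}")
    compared = diff = 0
    for x, y in zip(a, b):
        if x in _SKIP or y in _SKIP:
            continue
        compared += 1
        if x != y:
            diff += 1
    if compared == 0:
        raise ValueError("no comparable columns between the two rows")
    return diff / compared


@dataclass
class DistanceSummary:
    """Mean/variance of pairwise p-distances plus a bootstrap standard error."""

    region: RegionTag
    mean: float
    variance: float
    std_error: float
    n_pairs: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean <= 1.0):
            raise ValueError("p-distance mean must lie in [0, 1]")
        if self.variance < 0 or self.std_error < 0:
            raise ValueError("variance and standard error must be >= 0")


def domain_distance_summary(
    aligned_seqs: Sequence[str],
    region: RegionTag = RegionTag.WHOLE,
    n_bootstrap: int = 500,
    seed: int = 0,
) -> DistanceSummary:
    """Summarize pairwise p-distances of an aligned set of region sequences.

    The standard error of the mean distance is estimated by bootstrapping
    alignment columns (``n_bootstrap`` replicates, seeded).
    """
    rows = [getattr(s, "residues", s) for s in aligned_seqs]
    n = len(rows)
    if n < 2:
        raise ValueError("need at least 2 aligned sequences")
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise ValueError("aligned sequences must have equal length")
    dists = np.array([p_distance(a, b) for a, b in combinations(rows, 2)])
    mean = float(dists.mean())
    variance = float(dists.var())

    # column bootstrap: resample columns, recompute the mean pairwise distance
    arr = np.array([list(r) for r in rows])
    comparable = ~np.isin(arr, list(_SKIP))
    rng = np.random.default_rng(seed)
    boot_means = np.empty(n_bootstrap)
    pairs = list(combinations(range(n), 2))
    for rep in range(n_bootstrap):
        cols = rng.integers(0, length, size=length)
        sub = arr[:, cols]
        ok = comparable[:, cols]
        vals = []
        for i, j in pairs:
            mask = ok[i] & ok[j]
            m = int(mask.sum())
            if m == 0:
                continue
            vals.append(float((sub[i][mask] != sub[j][mask]).sum()) / m)
        boot_means[rep] = np.mean(vals) if vals else 0.0
    return DistanceSummary(
        region=region,
        mean=mean,
        variance=variance,
        std_error=float(boot_means.std()),
        n_pairs=len(pairs),
    )


def conservation_vs_accuracy(
    summaries: Mapping[RegionTag, DistanceSummary],
    model_cv_accuracies: Mapping[RegionTag, float],
) -> tuple[pd.DataFrame, float]:
    """Pair per-region diversity with per-region model accuracy.

    Returns a (region, mean_distance, cv_accuracy) table and the Spearman
    rank correlation between the two columns.
    """
    if set(summaries) != set(model_cv_accuracies):
        raise ValueError(
            f"region keys differ: {sorted(r.label for r in summaries)} vs "
            f"{sorted(r.label for r in model_cv_accuracies)}"
        )
    regions = sorted(summaries, key=lambda r: r.order)
    table = pd.DataFrame(
        {
            "region": [r.label for r in regions],
            "mean_distance": [summaries[r].mean for r in regions],
            "cv_accuracy": [model_cv_accuracies[r] for r in regions],
        }
    )
    rho = stats.spearmanr(table["mean_distance"], table["cv_accuracy"]).statistic
    return table, float(rho)


def align_region_sequences(seqs: Sequence, scheme: ScoringScheme | None = None) -> list[str]:
    """Naive reference-projected alignment of a set of region sequences.

    Equal-length inputs are returned as-is.  Otherwise each sequence is
    globally aligned to the longest one and projected onto its coordinates
    (columns inserted relative to the reference are dropped).  This is a
    deliberately simple utility for distance summaries, not a substitute for
    a progressive multiple aligner.
    """
    from Bio import Align

    rows = [getattr(s, "residues", s) for s in seqs]
    if len({len(r) for r in rows}) == 1:
        return list(rows)
    scheme = scheme or ScoringScheme()
    ref = max(rows, key=len)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = scheme.matrix
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    out = []
    for row in rows:
        if row == ref:
            out.append(ref)
            continue
        aln = aligner.align(ref, row)[0]
        ref_aln, row_aln = str(aln[0]), str(aln[1])
        projected = "".join(
            r for q, r in zip(ref_aln, row_aln) if q != "-"
        )
        out.append(projected)
    return out
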