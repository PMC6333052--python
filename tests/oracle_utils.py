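"""Independent oracles used by the test suite.

These deliberately do not share code with the package: the local-alignment
oracle is a three-state recursion over all alignment path prefixes, the
coiled-coil oracle a naive triple loop in log space, and the PROSITE oracle
a translation to Python regular expressions.
"""

from __future__ import annotations

import math
import re
from functools import lru_cache

import numpy as np

NEG = -(10 ** 9)


def sw_score_oracle(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Optimal local-alignment score by exhaustive consideration of all
    alignment paths (recursive three-state formulation; a gap of length L
    costs gap_open + L * gap_extend)."""

    @lru_cache(maxsize=None)
    def match(i: int, j: int) -> int:
        # best path ending with a[i-1] aligned to b[j-1]
        if i == 0 or j == 0:
            return NEG
        prev = max(0, match(i - 1, j - 1), gap_a(i - 1, j - 1), gap_b(i - 1, j - 1))
        return prev + int(matrix[a[i - 1], b[j - 1]])

    @lru_cache(maxsize=None)
    def gap_a(i: int, j: int) -> int:
        # best path ending with a[i-1] aligned to a gap
        if i == 0:
            return NEG
        return max(
            match(i - 1, j) - gap_open - gap_extend,
            gap_a(i - 1, j) - gap_extend,
        )

    @lru_cache(maxsize=None)
    def gap_b(i: int, j: int) -> int:
        if j == 0:
            return NEG
        return max(
            match(i, j - 1) - gap_open - gap_extend,
            gap_b(i, j - 1) - gap_extend,
        )

    best = 0
    for i in range(len(a) + 1):
        for j in range(len(b) + 1):
            best = max(best, match(i, j), gap_a(i, j), gap_b(i, j))
    return best


def coils_probabilities_oracle(seq: str, config) -> np.ndarray:
    """Per-residue coiled-coil probabilities by a naive triple loop
    (windows x frames x positions) in log space."""
    heptad = "abcdefg"
    n = len(seq)
    if n < min(config.window_widths):
        return np.zeros(n)
    final = np.zeros(n)
    for width in config.window_widths:
        if n < width:
            continue
        res_scores = [0.0] * n
        for start in range(0, n - width + 1):
            best = -math.inf
            for frame in range(7):
                num = 0.0
                den = 0.0
                for i in range(start, start + width):
                    pos = heptad[(i + frame) % 7]
                    props = config.matrix.get(seq[i], config.matrix["X"])
                    w = config.position_weights[pos]
                    num += w * math.log(props[heptad.index(pos)])
                    den += w
                best = max(best, math.exp(num / den))
            for i in range(start, start + width):
                res_scores[i] = max(res_scores[i], best)
        (cc_m, cc_s), (g_m, g_s) = config.gauss_params[width]
        for i in range(n):
            g_cc = math.exp(-((res_scores[i] - cc_m) ** 2) / (2 * cc_s ** 2)) / cc_s
            g_g = math.exp(-((res_scores[i] - g_m) ** 2) / (2 * g_s ** 2)) / g_s
            p = g_cc / (g_cc + g_g) if (g_cc + g_g) > 0 else 0.0
            final[i] = max(final[i], p)
    return final


_AA = "ACDEFGHIKLMNPQRSTVWY"


def prosite_to_regex(pattern, *, x_matches_all: bool = False) -> str:
    """Translate a parsed PROSITE pattern to an equivalent greedy regex."""
    parts = []
    for e in pattern.elements:
        if e.residues is None:
            body = f"[{_AA}X]"
        else:
            residues = "".join(sorted(e.residues))
            if x_matches_all:
                residues += "X"
            body = f"[{residues}]"
        if (e.min_repeat, e.max_repeat) == (1, 1):
            parts.append(body)
        else:
            parts.append(body + "{%d,%d}" % (e.min_repeat, e.max_repeat))
    rx = "".join(parts)
    if pattern.anchored_start:
        rx = r"\A" + rx
    if pattern.anchored_end:
        rx = rx + r"\Z"
    return rx


def regex_match_spans(pattern, seq: str, *, x_matches_all: bool = False) -> list[tuple[int, int]]:
    rx = re.compile(prosite_to_regex(pattern, x_matches_all=x_matches_all))
    return [(m.start(), m.end()) for m in rx.finditer(seq)]


def random_prosite_pattern(rng: np.random.Generator) -> str:
    """A random pattern from a constrained PROSITE grammar."""
    n_elems = int(rng.integers(1, 6))
    parts = []
    for _ in range(n_elems):
        kind = rng.choice(["single", "any", "set", "noneof"], p=[0.4, 0.25, 0.2, 0.15])
        if kind == "single":
            body = str(rng.choice(list(_AA)))
        elif kind == "any":
            body = "x"
        else:
            k = int(rng.integers(2, 5))
            members = "".join(rng.choice(list(_AA), size=k, replace=False))
            body = ("[%s]" if kind == "set" else "{%s}") % members
        r = rng.random()
        if r < 0.15:
            body += f"({int(rng.integers(1, 4))})"
        elif r < 0.3:
            lo = int(rng.integers(1, 3))
            hi = lo + int(rng.integers(0, 3))
            body += f"({lo},{hi})"
        parts.append(body)
    pattern = "-".join(parts)
    if rng.random() < 0.1:
        pattern = "<" + pattern
    if rng.random() < 0.1:
        pattern = pattern + ">"
    if rng.random() < 0.5:
        pattern += "."
    return pattern


def random_sequence(rng: np.random.Generator, max_len: int = 40, alphabet: str = "ACDEFGHX") -> str:
    n = int(rng.integers(1, max_len + 1))
    return "".join(rng.choice(list(alphabet), size=n))
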