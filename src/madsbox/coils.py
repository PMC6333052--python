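"""Coiled-coil propensity scoring in the COILS style.

A sliding window of width ``w`` is scored in each of the 7 heptad frame
offsets as the weighted geometric mean of per-residue propensities, with the
core positions a and d up-weighted (a,d = 2.5; b,c,e,f,g = 1.0).  The window
score is the best frame; each residue receives the maximum score over the
windows covering it; a per-width two-Gaussian likelihood ratio converts the
score into a coiled-coil probability, and the final per-residue probability
is the maximum over the configured window widths (14, 21, 28 by default).

The propensity matrix and per-width Gaussian parameters ship as versioned
TSV data files; every scoring routine is parameterized over whatever table
is loaded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

HEPTAD = "abcdefg"

#: Heptad position weights: core positions a/d vs. the rest.
DEFAULT_POSITION_WEIGHTS = {"a": 2.5, "b": 1.0, "c": 1.0, "d": 2.5, "e": 1.0, "f": 1.0, "g": 1.0}

DEFAULT_WINDOW_WIDTHS = (14, 21, 28)


def _data_path(name: str) -> Path:
    return Path(resources.files("madsbox").joinpath("data", name))


def load_propensity_matrix(path: str | Path | None = None) -> dict[str, np.ndarray]:
    """Load the residue-by-heptad-position propensity table.

    Returns a map residue -> length-7 array (positions a..g).  X is assigned
    a neutral propensity of 1.0 at every position.
    """
    path = Path(path) if path is not None else _data_path("coiled_coil_propensities.tsv")
    matrix: dict[str, np.ndarray] = {}
    header_seen = False
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split("\t")
        if not header_seen:
            if fields != ["residue", *HEPTAD]:
                raise ValueError(f"{path}: unexpected header {fields}")
            header_seen = True
            continue
        residue, *values = fields
        arr = np.array([float(v) for v in values], dtype=float)
        if len(arr) != 7 or (arr <= 0).any():
            raise ValueError(f"{path}: bad propensity row for {residue!r}")
        matrix[residue] = arr
    matrix.setdefault("X", np.ones(7))
    return matrix


def load_gaussian_params(path: str | Path | None = None) -> dict[int, tuple[tuple[float, float], tuple[float, float]]]:
    """Load per-width ((cc_mean, cc_sd), (glob_mean, glob_sd)) pairs."""
    path = Path(path) if path is not None else _data_path("coiled_coil_gaussians.tsv")
    params: dict[int, tuple[tuple[float, float], tuple[float, float]]] = {}
    header_seen = False
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split("\t")
        if not header_seen:
            header_seen = True
            continue
        w, cc_m, cc_s, g_m, g_s = fields
        params[int(w)] = ((float(cc_m), float(cc_s)), (float(g_m), float(g_s)))
    return params


@dataclass
class CoilsConfig:
    """Coiled-coil engine configuration (matrix, weights, windows, Gaussians)."""

    matrix_name: str = "MTIDK-style"
    matrix: dict[str, np.ndarray] = field(default_factory=load_propensity_matrix)
    position_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_POSITION_WEIGHTS)
    )
    window_widths: tuple[int, ...] = DEFAULT_WINDOW_WIDTHS
    gauss_params: dict[int, tuple[tuple[float, float], tuple[float, float]]] = field(
        default_factory=load_gaussian_params
    )

    def __post_init__(self) -> None:
        self.window_widths = tuple(sorted(self.window_widths))
        if any(w <= 0 for w in self.position_weights.values()):
            raise ValueError("position weights must be positive")
        for w in self.window_widths:
            if w not in self.gauss_params:
                raise ValueError(f"no Gaussian parameters for window width {w}")

    @classmethod
    def default(cls) -> "CoilsConfig":
        return cls()


@dataclass
class CoilsProfile:
    """Per-residue coiled-coil probabilities plus per-window score tracks."""

    probabilities: np.ndarray
    per_window_scores: dict[int, np.ndarray]
    too_short: bool = False


def _log_tracks(seq: str, config: CoilsConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue weighted-log-propensity and weight tracks for all 7 frames.

    Returns arrays of shape (n, 7): entry (i, f) is for residue i when the
    sequence heptad frame is offset f (residue i sits at heptad position
    ``(i + f) % 7``).
    """
    n = len(seq)
    logprop = np.empty((n, 7))
    weights = np.empty((n, 7))
    wvec = np.array([config.position_weights[p] for p in HEPTAD])
    for i, res in enumerate(seq):
        props = config.matrix.get(res)
        if props is None:
            props = config.matrix["X"]
        lp = np.log(props)
        for f in range(7):
            pos = (i + f) % 7
            logprop[i, f] = lp[pos]
            weights[i, f] = wvec[pos]
    return logprop, weights


def _window_scores(seq: str, width: int, config: CoilsConfig) -> tuple[np.ndarray, np.ndarray]:
    """Best-frame window scores for every placement of one window width.

    Returns (scores, frames): scores[s] is the best weighted-geometric-mean
    propensity of window [s, s+width), frames[s] the frame achieving it.
    """
    logprop, weights = _log_tracks(seq, config)
    wlp = logprop * weights
    # cumulative sums along sequence axis, per frame
    c_wlp = np.vstack([np.zeros(7), np.cumsum(wlp, axis=0)])
    c_w = np.vstack([np.zeros(7), np.cumsum(weights, axis=0)])
    n = len(seq)
    n_windows = n - width + 1
    sums = c_wlp[width:] - c_wlp[:n_windows]
    wts = c_w[width:] - c_w[:n_windows]
    frame_scores = np.exp(sums / wts)  # (n_windows, 7)
    frames = np.argmax(frame_scores, axis=1)
    scores = frame_scores[np.arange(n_windows), frames]
    return scores, frames


def _gauss(x, mean: float, sd: float):
    return np.exp(-((x - mean) ** 2) / (2.0 * sd * sd)) / sd


def score_to_probability(score, width: int, config: CoilsConfig):
    """Two-Gaussian likelihood ratio P = G_cc / (G_cc + G_glob)."""
    (cc_m, cc_s), (g_m, g_s) = config.gauss_params[width]
    g_cc = _gauss(score, cc_m, cc_s)
    g_g = _gauss(score, g_m, g_s)
    denom = g_cc + g_g
    return np.where(denom > 0, g_cc / np.where(denom > 0, denom, 1.0), 0.0)


def coils_profile(sequence, config: CoilsConfig | None = None) -> CoilsProfile:
    """Per-residue coiled-coil probability profile of a sequence.

    Sequences shorter than the smallest window width get an all-zero profile
    flagged ``too_short``.
    """
    if config is None:
        config = CoilsConfig.default()
    seq = getattr(sequence, "residues", sequence)
    n = len(seq)
    if n < min(config.window_widths):
        return CoilsProfile(
            probabilities=np.zeros(n), per_window_scores={}, too_short=True
        )
    probabilities = np.zeros(n)
    per_window_scores: dict[int, np.ndarray] = {}
    for width in config.window_widths:
        if n < width:
            continue
        scores, _ = _window_scores(seq, width, config)
        # per-residue score: max over windows covering the residue
        res_scores = np.zeros(n)
        for s, sc in enumerate(scores):
            seg = res_scores[s: s + width]
            np.maximum(seg, sc, out=seg)
        per_window_scores[width] = res_scores
        probs = score_to_probability(res_scores, width, config)
        np.maximum(probabilities, probs, out=probabilities)
    return CoilsProfile(
        probabilities=probabilities, per_window_scores=per_window_scores
    )


@dataclass(frozen=True)
class CoilSegment:
    start: int
    end: int
    score: float
    probability: float
    frame: int
    width: int


def find_coil_segment(
    sequence,
    config: CoilsConfig | None = None,
    *,
    prob_threshold: float = 0.5,
    pivot: float = 1.2,
) -> Optional[CoilSegment]:
    """Locate the best coiled-coil segment of a sequence, or None.

    Detection uses the widest configured window (large windows suppress
    random-sequence score fluctuations): the best-scoring placement must meet
    ``prob_threshold``.  Boundaries are then refined by maximal-sum extension
    of per-residue log-odds (log propensity relative to ``pivot``) in the
    locked heptad frame, which localizes the coil edges to within a few
    residues.
    """
    if config is None:
        config = CoilsConfig.default()
    seq = getattr(sequence, "residues", sequence)
    n = len(seq)
    width = max(config.window_widths)
    usable = [w for w in config.window_widths if w <= n]
    if not usable:
        return None
    width = max(usable)
    scores, frames = _window_scores(seq, width, config)
    best = int(np.argmax(scores))
    best_score = float(scores[best])
    prob = float(score_to_probability(np.array(best_score), width, config))
    if prob < prob_threshold:
        return None
    frame = int(frames[best])
    logprop, weights = _log_tracks(seq, config)
    lo = weights[:, frame] * (logprop[:, frame] - math.log(pivot))
    start, end = best, best + width
    # extend left: take the prefix (going leftwards) with maximal sum
    run, best_run, take = 0.0, 0.0, 0
    for i in range(start - 1, -1, -1):
        run += lo[i]
        if run > best_run:
            best_run, take = run, start - i
    start -= take
    # extend right symmetrically
    run, best_run, take = 0.0, 0.0, 0
    for i in range(end, n):
        run += lo[i]
        if run > best_run:
            best_run, take = run, i - end + 1
    end += take
    return CoilSegment(
        start=start, end=end, score=best_score, probability=prob,
        frame=frame, width=width,
    )
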