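"""Stage-1 domain judgement: MIKC membership and M/I/K/C segmentation.

A query protein is accepted as MIKC-type when it carries a match of the
configured MADS (M) domain pattern, written in PROSITE pattern syntax.  The
keratin-like (K) domain is located as the best coiled-coil segment downstream
of M using the coiled-coil engine (:mod:`madsbox.coils`); the intervening (I)
domain is the gap between M and K, and the C-terminal (C) domain is the tail
after K.

The PROSITE pattern grammar supported here: elements separated by ``-``;
single residue letters; ``[..]`` any-of; ``{..}`` none-of; ``x`` any residue;
optional ``(n)`` or ``(n,m)`` repeat counts; ``<``/``>`` anchors; optional
trailing ``.``.  Matching is leftmost-greedy with non-overlapping scanning,
exactly the semantics of a translation to a greedy regular expression.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

from . import coils as _coils

_STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"


class PatternSyntaxError(ValueError):
    """Raised for malformed PROSITE pattern strings (with position info)."""


class RegionTag(Enum):
    """Region labels: the whole sequence or one of the four MIKC domains.

    ``C_TERM`` names the MADS C domain (avoiding collision with the C gene
    class).  ``order`` gives the N-to-C domain order used for span layout.
    """

    WHOLE = ("whole", 0)
    M = ("M", 1)
    I = ("I", 2)
    K = ("K", 3)
    C_TERM = ("C", 4)

    def __init__(self, label: str, order: int) -> None:
        self.label = label
        self.order = order

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


#: The four domains in N-to-C order.
DOMAIN_ORDER: tuple[RegionTag, ...] = (RegionTag.M, RegionTag.I, RegionTag.K, RegionTag.C_TERM)

_DOMAIN_LETTER = {RegionTag.M: "M", RegionTag.I: "I", RegionTag.K: "K", RegionTag.C_TERM: "C"}


@dataclass
class DomainAnnotation:
    """M/I/K/C span map plus the MIKC membership flag for one sequence.

    Spans are 0-based half-open, within sequence bounds, mutually
    non-overlapping and ordered M < I < K < C.  ``is_mikc`` is true exactly
    when an M span is present.
    """

    sequence_id: str
    spans: dict[RegionTag, tuple[int, int]] = field(default_factory=dict)
    is_mikc: bool = False
    sequence_length: Optional[int] = None

    def __post_init__(self) -> None:
        if RegionTag.WHOLE in self.spans:
            raise ValueError("WHOLE is not an annotatable span")
        prev_end = None
        for tag in DOMAIN_ORDER:
            if tag not in self.spans:
                continue
            start, end = self.spans[tag]
            if not (0 <= start < end):
                raise ValueError(f"{self.sequence_id}: bad span {tag}: {(start, end)}")
            if self.sequence_length is not None and end > self.sequence_length:
                raise ValueError(
                    f"{self.sequence_id}: span {tag} {(start, end)} exceeds "
                    f"sequence length {self.sequence_length}"
                )
            if prev_end is not None and start < prev_end:
                raise ValueError(
                    f"{self.sequence_id}: spans overlap or are out of M<I<K<C order"
                )
            prev_end = end
        if self.is_mikc != (RegionTag.M in self.spans):
            raise ValueError(
                f"{self.sequence_id}: is_mikc must be true iff an M span is present"
            )

    @property
    def present_regions(self) -> frozenset[RegionTag]:
        return frozenset(self.spans)

    def shifted(self, offset: int) -> "DomainAnnotation":
        spans = {t: (s + offset, e + offset) for t, (s, e) in self.spans.items()}
        return replace(self, spans=spans)


def domain_content_key(annotation: DomainAnnotation) -> str:
    """Canonical domain-content string, e.g. ``"MIKC"``, ``"M"``, ``"KC"``.

    Concatenates the letters of the present regions in M, I, K, C order; the
    empty string means no recognized domain.  Injective over the subsets of
    the four domains.
    """
    return "".join(
        _DOMAIN_LETTER[t] for t in DOMAIN_ORDER if t in annotation.spans
    )


# ---------------------------------------------------------------------------
# PROSITE patterns
# ---------------------------------------------------------------------------

#: Sentinel residue set meaning "any residue" (PROSITE ``x``).
ANY = None


@dataclass(frozen=True)
class PatternElement:
    """One pattern element: an allowed residue set and a repeat range."""

    residues: Optional[frozenset[str]]  # None means ANY (PROSITE x)
    min_repeat: int = 1
    max_repeat: int = 1

    def allows(self, residue: str, *, x_matches_all: bool = False) -> bool:
        if self.residues is ANY:
            return True
        if residue == "X":
            return x_matches_all
        return residue in self.residues


@dataclass(frozen=True)
class PrositePattern:
    """A parsed PROSITE pattern (element list plus anchors)."""

    raw: str
    elements: tuple[PatternElement, ...]
    anchored_start: bool = False
    anchored_end: bool = False

    @property
    def min_length(self) -> int:
        return sum(e.min_repeat for e in self.elements)


_REPEAT_RE = re.compile(r"\((\d+)(?:,(\d+))?\)$")


def parse_prosite(pattern_string: str) -> PrositePattern:
    """Parse a PROSITE pattern string into a :class:`PrositePattern`.

    Raises :class:`PatternSyntaxError` with the offending element position on
    unbalanced brackets, empty residue classes or invalid repeat ranges.
    """
    raw = pattern_string.strip()
    text = raw
    if text.endswith("."):
        text = text[:-1]
    anchored_start = text.startswith("<")
    if anchored_start:
        text = text[1:]
    anchored_end = text.endswith(">")
    if anchored_end:
        text = text[:-1]
    if not text:
        raise PatternSyntaxError("empty pattern")
    elements: list[PatternElement] = []
    for pos, token in enumerate(text.split("-")):
        token = token.strip()
        if not token:
            raise PatternSyntaxError(f"element {pos}: empty element")
        min_rep, max_rep = 1, 1
        m = _REPEAT_RE.search(token)
        if m:
            min_rep = int(m.group(1))
            max_rep = int(m.group(2)) if m.group(2) is not None else min_rep
            if min_rep < 1 or min_rep > max_rep:
                raise PatternSyntaxError(
                    f"element {pos}: invalid repeat range ({min_rep},{max_rep})"
                )
            token = token[: m.start()]
        if not token:
            raise PatternSyntaxError(f"element {pos}: repeat without a body")
        if token == "x":
            residues: Optional[frozenset[str]] = ANY
        elif token.startswith("[") or token.startswith("{"):
            open_b, close_b = ("[", "]") if token[0] == "[" else ("{", "}")
            if not token.endswith(close_b):
                raise PatternSyntaxError(f"element {pos}: unbalanced {open_b!r}")
            inner = token[1:-1]
            if not inner:
                raise PatternSyntaxError(f"element {pos}: empty residue class")
            bad = set(inner) - set(_STANDARD_AA)
            if bad:
                raise PatternSyntaxError(
                    f"element {pos}: invalid residue(s) {sorted(bad)} in class"
                )
            members = frozenset(inner)
            if open_b == "{":
                members = frozenset(_STANDARD_AA) - members
                if not members:
                    raise PatternSyntaxError(f"element {pos}: none-of class excludes everything")
            residues = members
        elif len(token) == 1 and token in _STANDARD_AA:
            residues = frozenset(token)
        else:
            raise PatternSyntaxError(f"element {pos}: unrecognized element {token!r}")
        elements.append(PatternElement(residues, min_rep, max_rep))
    return PrositePattern(
        raw=raw,
        elements=tuple(elements),
        anchored_start=anchored_start,
        anchored_end=anchored_end,
    )


def render_prosite(pattern: PrositePattern) -> str:
    """Render a pattern back to normalized PROSITE syntax.

    ``parse_prosite(render_prosite(p))`` reproduces ``p`` up to the raw text.
    """
    parts = []
    for e in pattern.elements:
        if e.residues is ANY:
            body = "x"
        elif len(e.residues) == 1:
            body = next(iter(e.residues))
        else:
            body = "[" + "".join(sorted(e.residues)) + "]"
        if (e.min_repeat, e.max_repeat) == (1, 1):
            parts.append(body)
        elif e.min_repeat == e.max_repeat:
            parts.append(f"{body}({e.min_repeat})")
        else:
            parts.append(f"{body}({e.min_repeat},{e.max_repeat})")
    core = "-".join(parts)
    if pattern.anchored_start:
        core = "<" + core
    if pattern.anchored_end:
        core = core + ">"
    return core + "."


def _match_here(
    pattern: PrositePattern, seq: str, start: int, *, x_matches_all: bool
) -> Optional[int]:
    """Greedy backtracking match attempt anchored at ``start``.

    Returns the end index of the leftmost-greedy match, or None.
    """
    elements = pattern.elements
    n = len(seq)

    def backtrack(pos: int, elem_idx: int) -> Optional[int]:
        if elem_idx == len(elements):
            if pattern.anchored_end and pos != n:
                return None
            return pos
        elem = elements[elem_idx]
        # Count how many repeats are possible (greedy: try longest first).
        max_take = 0
        while (
            max_take < elem.max_repeat
            and pos + max_take < n
            and elem.allows(seq[pos + max_take], x_matches_all=x_matches_all)
        ):
            max_take += 1
        for take in range(max_take, elem.min_repeat - 1, -1):
            end = backtrack(pos + take, elem_idx + 1)
            if end is not None:
                return end
        return None

    return backtrack(start, 0)


def match_pattern(
    pattern: PrositePattern,
    sequence,
    *,
    x_matches_all: bool = False,
) -> list[tuple[int, int]]:
    """All leftmost-greedy, non-overlapping matches of ``pattern``.

    ``sequence`` may be a string or any object with a ``residues`` attribute.
    Scanning proceeds left to right; after a match at ``(s, e)`` scanning
    resumes at ``e``.  An X in the sequence matches only the ``x`` (any)
    element unless ``x_matches_all`` is set.
    """
    seq = getattr(sequence, "residues", sequence)
    matches: list[tuple[int, int]] = []
    pos = 0
    n = len(seq)
    while pos <= n - pattern.min_length:
        if pattern.anchored_start and pos > 0:
            break
        end = _match_here(pattern, seq, pos, x_matches_all=x_matches_all)
        if end is not None:
            matches.append((pos, end))
            pos = end if end > pos else pos + 1
        else:
            pos += 1
    return matches


def read_pattern_file(path: str | Path) -> list[PrositePattern]:
    """Read a pattern file: one PROSITE pattern per line, ``#`` comments."""
    patterns = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            patterns.append(parse_prosite(line))
    return patterns


# ---------------------------------------------------------------------------
# Domain annotation
# ---------------------------------------------------------------------------

#: Default M-domain pattern: the conserved N-terminal core of the plant MADS
#: domain (consensus MGRGRVELKRIEN...).  Shipped as config, overridable.
DEFAULT_M_PATTERN = "M-[GA]-R-[GS]-[KR]-[ILV]-[DEQ]-[ILM]-[KR]-[KR]-[ILV]-[DE]-N."


@dataclass
class DomainScanConfig:
    """Configuration for stage-1 domain judgement.

    ``m_length`` is the fixed MADS-domain length the M-pattern match is
    extended to (the MADS domain is a conserved ~56-57 residue region);
    ``min_i_length`` is the minimum gap between M and K that is called an
    I domain; K detection settings are delegated to the coiled-coil engine.
    """

    m_pattern: PrositePattern = field(
        default_factory=lambda: parse_prosite(DEFAULT_M_PATTERN)
    )
    m_length: int = 57
    min_i_length: int = 5
    min_k_length: int = 14
    k_prob_threshold: float = 0.5
    coils: _coils.CoilsConfig = field(default_factory=_coils.CoilsConfig.default)
    x_matches_all: bool = False


def annotate_domains(sequence, config: DomainScanConfig | None = None) -> DomainAnnotation:
    """Segment a sequence into M/I/K/C domains and decide MIKC membership.

    The M span is the first (leftmost) M-pattern match extended to
    ``config.m_length`` residues (truncated at the sequence end).  The K span
    is the best coiled-coil segment downstream of M that meets the
    probability threshold; I is the gap between M and K when long enough, and
    C is the tail after K.  A sequence without an M-pattern match gets an
    empty annotation with ``is_mikc=False``.
    """
    if config is None:
        config = DomainScanConfig()
    seq = getattr(sequence, "residues", sequence)
    seq_id = getattr(sequence, "id", "<anonymous>")
    if not seq:
        raise ValueError("cannot annotate an empty sequence")
    n = len(seq)
    matches = match_pattern(config.m_pattern, seq, x_matches_all=config.x_matches_all)
    if not matches:
        return DomainAnnotation(sequence_id=seq_id, spans={}, is_mikc=False, sequence_length=n)
    m_start = matches[0][0]
    m_end = min(m_start + config.m_length, n)
    spans: dict[RegionTag, tuple[int, int]] = {RegionTag.M: (m_start, m_end)}

    k_span: Optional[tuple[int, int]] = None
    tail = seq[m_end:]
    if len(tail) >= config.min_k_length:
        seg = _coils.find_coil_segment(
            tail, config.coils, prob_threshold=config.k_prob_threshold
        )
        if seg is not None:
            k_start, k_end = seg.start + m_end, seg.end + m_end
            if k_end - k_start >= config.min_k_length:
                k_span = (k_start, k_end)
    if k_span is not None:
        if k_span[0] - m_end >= config.min_i_length:
            spans[RegionTag.I] = (m_end, k_span[0])
        spans[RegionTag.K] = k_span
        if k_span[1] < n:
            spans[RegionTag.C_TERM] = (k_span[1], n)
    return DomainAnnotation(
        sequence_id=seq_id, spans=spans, is_mikc=True, sequence_length=n
    )


def write_annotations(annotations: Iterable[DomainAnnotation], path: str | Path) -> None:
    """Write annotations as TSV: sequence_id, region, start, end."""
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("sequence_id\tregion\tstart\tend\n")
        for ann in annotations:
            for tag in DOMAIN_ORDER:
                if tag in ann.spans:
                    s, e = ann.spans[tag]
                    fh.write(f"{ann.sequence_id}\t{_DOMAIN_LETTER[tag]}\t{s}\t{e}\n")
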