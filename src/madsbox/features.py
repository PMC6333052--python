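"""Feature encoding for MADS-box classification.

Three feature families are produced from a (whole or domain-restricted)
sequence:

* **class similarity** — for each of the eight gene classes, the mean
  bit score of local alignments against that class's reference sequences,
  keeping only hits with e-value below a threshold (default 1e-5) and
  encoding 0 when no hit passes;
* **DNA-binding propensity of the M domain** — a fixed 57-position layout of
  per-residue (side-chain pKa, hydrophobicity, molecular mass) triplets,
  each scale min-max normalized over the 20 standard residues.  This is a
  self-contained surrogate for the retired BindN predictor, built from the
  same three input scales BindN used;
* **coiled-coil summary of the K domain** — [mean, max, fraction >= 0.5] of
  the per-residue coiled-coil probability profile over the K span.

Reference databases are built per region (whole sequence plus the four
domains) from an annotated training set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np

from .align import ScoringScheme, local_align
from .coils import CoilsConfig, CoilsProfile, coils_profile
from .domain_scan import DomainAnnotation, RegionTag, DOMAIN_ORDER
from .seqio import CLASS_ORDER, GeneClass, LabeledDataset, ProteinSequence, STANDARD_AA

logger = logging.getLogger(__name__)

DEFAULT_EVALUE_THRESHOLD = 1e-5

#: Fixed M-domain layout length for the DNA-binding block (3 scales x 57).
BINDN_POSITIONS = 57
BINDN_BLOCK_LENGTH = 3 * BINDN_POSITIONS

COILS_BLOCK_LENGTH = 3
CLASS_BLOCK_LENGTH = len(CLASS_ORDER)


class RegionUnavailableError(ValueError):
    """A feature recipe needs a region the annotation does not provide."""

    def __init__(self, region: RegionTag):
        self.region = region
        super().__init__(f"region unavailable: {region.label}")


@dataclass
class ReferenceDatabase:
    """Region-restricted reference sequences grouped by gene class."""

    region: RegionTag
    per_class: dict[GeneClass, list[ProteinSequence]]

    def __post_init__(self) -> None:
        for cls in CLASS_ORDER:
            self.per_class.setdefault(cls, [])

    @property
    def n_sequences(self) -> int:
        return sum(len(v) for v in self.per_class.values())


@dataclass(frozen=True)
class ClassSimilarityVector:
    """The eight per-class average bit-score features (fixed class order)."""

    values: np.ndarray
    evalue_threshold: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (CLASS_BLOCK_LENGTH,):
            raise ValueError(f"expected {CLASS_BLOCK_LENGTH} values, got {v.shape}")
        if not np.all(np.isfinite(v)) or (v < 0).any():
            raise ValueError("class-similarity values must be finite and >= 0")
        object.__setattr__(self, "values", v)


@dataclass
class EncoderConfigs:
    """Shared encoder settings (coiled-coil config and e-value gate)."""

    coils: CoilsConfig = field(default_factory=CoilsConfig.default)
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD


def region_subsequence(
    seq: ProteinSequence, annotation: DomainAnnotation, region: RegionTag
) -> ProteinSequence:
    """The region-restricted subsequence; WHOLE returns the sequence itself."""
    if region is RegionTag.WHOLE:
        return seq
    if region not in annotation.spans:
        raise RegionUnavailableError(region)
    return seq.subsequence(annotation.spans[region])


def build_reference_databases(
    train: LabeledDataset,
    annotations: Mapping[str, DomainAnnotation] | None = None,
) -> dict[RegionTag, ReferenceDatabase]:
    """Five region databases (whole + M/I/K/C) from an annotated training set.

    Sequences lacking a region are simply absent from that region's database;
    the WHOLE database contains every training sequence.  A training set
    missing a class entirely is an error.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    counts = train.class_counts()
    missing = [c.value for c in CLASS_ORDER if counts[c] == 0]
    if missing:
        raise ValueError(f"training set has no sequences for class(es): {missing}")
    if annotations is None:
        annotations = {
            sid: ann for sid, ann in train.annotations.items() if ann is not None
        }
    dbs: dict[RegionTag, ReferenceDatabase] = {}
    for region in (RegionTag.WHOLE, *DOMAIN_ORDER):
        per_class: dict[GeneClass, list[ProteinSequence]] = {c: [] for c in CLASS_ORDER}
        for seq, cls, _ in train.entries:
            if region is RegionTag.WHOLE:
                per_class[cls].append(seq)
                continue
            ann = annotations.get(seq.id)
            if ann is None:
                raise ValueError(f"training sequence {seq.id!r} has no domain annotation")
            if region in ann.spans:
                per_class[cls].append(region_subsequence(seq, ann, region))
        dbs[region] = ReferenceDatabase(region=region, per_class=per_class)
    return dbs


def encode_class_similarity(
    query,
    db: ReferenceDatabase,
    scheme: ScoringScheme | None = None,
    exclude_self_id: str | None = None,
    evalue_threshold: float = DEFAULT_EVALUE_THRESHOLD,
) -> ClassSimilarityVector:
    """Eight per-class average bit scores of hits passing the e-value gate.

    For each class the query is aligned against every member (excluding
    ``exclude_self_id`` so a reference is never compared with itself); hits
    with ``evalue < evalue_threshold`` are kept and averaged; a class with no
    passing hit encodes 0.
    """
    if scheme is None:
        scheme = ScoringScheme()
    values = np.zeros(CLASS_BLOCK_LENGTH)
    for idx, cls in enumerate(CLASS_ORDER):
        bits = [
            hit.bit_score
            for member in db.per_class[cls]
            if member.id != exclude_self_id
            for hit in [local_align(query, member, scheme)]
            if hit.evalue < evalue_threshold
        ]
        if bits:
            # sorted summation keeps the mean invariant to database order
            values[idx] = float(np.mean(sorted(bits)))
    return ClassSimilarityVector(values=values, evalue_threshold=evalue_threshold)


# ---------------------------------------------------------------------------
# DNA-binding propensity block (M domain)
# ---------------------------------------------------------------------------

# Side-chain pKa (non-ionizable side chains set to the neutral 7.0),
# Kyte-Doolittle hydropathy, and residue molecular mass (Da).
_SIDE_CHAIN_PKA = {
    "D": 3.65, "E": 4.25, "H": 6.00, "C": 8.30, "Y": 10.07, "K": 10.53,
    "R": 12.48,
}
_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
_RESIDUE_MASS = {
    "A": 89.09, "R": 174.20, "N": 132.12, "D": 133.10, "C": 121.16,
    "E": 147.13, "Q": 146.15, "G": 75.07, "H": 155.16, "I": 131.17,
    "L": 131.17, "K": 146.19, "M": 149.21, "F": 165.19, "P": 115.13,
    "S": 105.09, "T": 119.12, "W": 204.23, "Y": 181.19, "V": 117.15,
}


def _normalized_scales() -> dict[str, np.ndarray]:
    """Per-residue (pKa, hydropathy, mass) triplets, min-max normalized
    over the 20 standard residues; X encodes as the scale means."""
    scales = []
    for table, default in ((_SIDE_CHAIN_PKA, 7.0), (_HYDROPATHY, None), (_RESIDUE_MASS, None)):
        vals = np.array([table.get(r, default) for r in STANDARD_AA], dtype=float)
        lo, hi = vals.min(), vals.max()
        scales.append((vals - lo) / (hi - lo))
    triplets = {r: np.array([s[i] for s in scales]) for i, r in enumerate(STANDARD_AA)}
    triplets["X"] = np.array([s.mean() for s in scales])
    return triplets


_SCALE_TRIPLETS = _normalized_scales()


def encode_bindn_block(m_seq, positions: int = BINDN_POSITIONS) -> np.ndarray:
    """Fixed-length DNA-binding propensity encoding of the M-domain sequence.

    Per-position triplets (normalized side-chain pKa, hydropathy, residue
    mass) laid out for positions 0..positions-1; positions past the sequence
    end are zero-padded.  Length is always ``3 * positions`` (171 by default).
    """
    seq = getattr(m_seq, "residues", m_seq)
    if not seq:
        raise ValueError("cannot encode an empty M-domain sequence")
    out = np.zeros(3 * positions)
    for i, res in enumerate(seq[:positions]):
        out[3 * i: 3 * i + 3] = _SCALE_TRIPLETS[res]
    return out


def encode_coils_block(profile: CoilsProfile, k_span: tuple[int, int]) -> np.ndarray:
    """[mean, max, fraction >= 0.5] of the probability profile over a span."""
    start, end = k_span
    if not (0 <= start < end <= len(profile.probabilities)):
        raise ValueError(f"empty or out-of-bounds span {k_span}")
    window = profile.probabilities[start:end]
    return np.array([
        float(window.mean()),
        float(window.max()),
        float((window >= 0.5).mean()),
    ])


# ---------------------------------------------------------------------------
# Feature vector assembly
# ---------------------------------------------------------------------------

@dataclass
class FeatureVector:
    """Named, ordered feature blocks plus their flat concatenation."""

    recipe_id: str
    region_scope: frozenset[RegionTag]
    blocks: dict[str, np.ndarray]
    flat: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.flat)):
            raise ValueError(f"non-finite feature values in recipe {self.recipe_id!r}")


def block_length(kind: str) -> int:
    return {"sim": CLASS_BLOCK_LENGTH, "bindn": BINDN_BLOCK_LENGTH, "coils": COILS_BLOCK_LENGTH}[kind]


def compute_block(
    seq: ProteinSequence,
    annotation: DomainAnnotation,
    kind: str,
    region: RegionTag,
    refdbs: Mapping[RegionTag, ReferenceDatabase],
    scheme: ScoringScheme,
    configs: EncoderConfigs,
    exclude_self_id: str | None = None,
) -> np.ndarray:
    """One feature block for one sequence (raises RegionUnavailableError)."""
    sub = region_subsequence(seq, annotation, region)
    if kind == "sim":
        vec = encode_class_similarity(
            sub, refdbs[region], scheme,
            exclude_self_id=exclude_self_id,
            evalue_threshold=configs.evalue_threshold,
        )
        return vec.values
    if kind == "bindn":
        return encode_bindn_block(sub)
    if kind == "coils":
        profile = coils_profile(sub, configs.coils)
        return encode_coils_block(profile, (0, len(sub.residues)))
    raise ValueError(f"unknown block kind {kind!r}")


def build_feature_vector(
    seq: ProteinSequence,
    annotation: DomainAnnotation,
    recipe,
    refdbs: Mapping[RegionTag, ReferenceDatabase],
    scheme: ScoringScheme | None = None,
    configs: EncoderConfigs | None = None,
    exclude_self_id: str | None = None,
) -> FeatureVector:
    """Assemble the feature vector of a registered recipe for one sequence.

    ``recipe`` is a :class:`~madsbox.classify.ModelRecipe` or a recipe id
    string.  Blocks are computed on the region-restricted subsequences and
    concatenated in the recipe's registered order; a missing required region
    raises :class:`RegionUnavailableError`.
    """
    if isinstance(recipe, str):
        from .classify import get_recipe  # lazy: classify imports this module

        recipe = get_recipe(recipe)
    if scheme is None:
        scheme = ScoringScheme()
    if configs is None:
        configs = EncoderConfigs()
    blocks: dict[str, np.ndarray] = {}
    for kind, region in recipe.blocks:
        blocks[f"{kind}:{region.label}"] = compute_block(
            seq, annotation, kind, region, refdbs, scheme, configs,
            exclude_self_id=exclude_self_id,
        )
    flat = np.concatenate(list(blocks.values())) if blocks else np.zeros(0)
    return FeatureVector(
        recipe_id=recipe.recipe_id,
        region_scope=frozenset(r for _, r in recipe.blocks),
        blocks=blocks,
        flat=flat,
    )


def write_features_tsv(rows: Iterable[tuple[str, np.ndarray]], path) -> None:
    """Export flat feature vectors as TSV (id, then one column per feature)."""
    from pathlib import Path

    rows = list(rows)
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        if rows:
            n = len(rows[0][1])
            fh.write("sequence_id\t" + "\t".join(f"f{i}" for i in range(n)) + "\n")
        for sid, vec in rows:
            fh.write(sid + "\t" + "\t".join(f"{v:.6g}" for v in vec) + "\n")


def write_features_svm(rows: Iterable[tuple[str, np.ndarray]], labels: Mapping[str, int], path) -> None:
    """Sparse ``label index:value`` text lines (1-based indices), the common
    SVM training format."""
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for sid, vec in rows:
            items = " ".join(
                f"{i + 1}:{v:.6g}" for i, v in enumerate(vec) if v != 0.0
            )
            fh.write(f"{labels[sid]} {items}\n")
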