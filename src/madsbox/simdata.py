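"""Synthetic eight-class MIKC-like protein families with controlled divergence.

The generator emulates the structure of a curated MIKC reference set: a
common root sequence with the four-domain layout M(57) + I(30) + K(70) +
C(60) gives rise to one ancestor per gene class (per-region "extra"
substitution rates concentrate class-level divergence in the C domain, then
I, K, M — the diversity ordering observed in real MADS families), and class
members diverge from their ancestor at a within-class rate.  Substitutions
are drawn from a BLOSUM62-conditional replacement kernel so alignment
statistics stay realistic.

Three kinds of sites are protected from substitution, emulating purifying
selection and guaranteeing that stage-1 detection works by construction:
the M-domain pattern core, the hydrophobic a/d core positions of the K
heptads, and a class-specific signature 6-mer planted in the C domain (the
learnable class signal that makes the C domain the most discriminative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .domain_scan import (
    DEFAULT_M_PATTERN,
    DOMAIN_ORDER,
    DomainAnnotation,
    PrositePattern,
    RegionTag,
    parse_prosite,
)
from .seqio import (
    CLASS_ORDER,
    GeneClass,
    LabeledDataset,
    ProteinSequence,
    STANDARD_AA,
)

#: Conserved plant MADS-domain consensus used as the M-region root.
M_CONSENSUS = "MGRGRVELKRIENKINRQVTFSKRRNGLLKKAYELSVLCDAEVALIIFSNRGKLYEF"

#: Number of leading M positions protected from substitution (pattern core).
M_PROTECTED = 13

_HYDROPHOBIC_A = "LIVM"
_HYDROPHOBIC_D = "LLMA"  # d-position pool, leucine-biased
_POLAR_HEPTAD = "EKQRASND"
_LINKER_POOL = "ASTGPQNEDKRHSGP"
_GENERAL_POOL = STANDARD_AA

DEFAULT_REGION_LENGTHS = {
    RegionTag.M: 57,
    RegionTag.I: 30,
    RegionTag.K: 70,
    RegionTag.C_TERM: 60,
}

DEFAULT_BETWEEN_CLASS_RATES = {
    RegionTag.M: 0.05,
    RegionTag.I: 0.25,
    RegionTag.K: 0.20,
    RegionTag.C_TERM: 0.40,
}

SIGNATURE_START = 10
SIGNATURE_LENGTH = 6


@dataclass
class SyntheticFamilySpec:
    """Generator parameters; the defaults define the benchmark conditions."""

    seed: int
    n_per_class: int = 10
    region_lengths: dict[RegionTag, int] = field(
        default_factory=lambda: dict(DEFAULT_REGION_LENGTHS)
    )
    within_class_sub_rate: float = 0.10
    between_class_extra_rate: dict[RegionTag, float] = field(
        default_factory=lambda: dict(DEFAULT_BETWEEN_CLASS_RATES)
    )
    heptad_in_k: bool = True
    m_pattern: PrositePattern = field(
        default_factory=lambda: parse_prosite(DEFAULT_M_PATTERN)
    )

    def __post_init__(self) -> None:
        if self.n_per_class < 2:
            raise ValueError("n_per_class must be >= 2")
        if not (0 <= self.within_class_sub_rate < 1):
            raise ValueError("within_class_sub_rate must be in [0, 1)")
        for region, rate in self.between_class_extra_rate.items():
            if not (0 <= rate < 1):
                raise ValueError(f"between-class rate for {region} must be in [0, 1)")
        if self.region_lengths[RegionTag.M] < self.m_pattern.min_length:
            raise ValueError("M region shorter than the M pattern")


def blosum62_replacement_kernel() -> tuple[str, np.ndarray]:
    """Conditional replacement probabilities P(b | a) for b != a.

    Row-normalized exp(S(a, b) / 2) over the 20 standard residues with the
    diagonal removed: high-scoring (conservative) replacements are favoured,
    as in real divergence, keeping alignment statistics realistic.
    """
    m = substitution_matrices.load("BLOSUM62")
    n = len(STANDARD_AA)
    K = np.zeros((n, n))
    for i, a in enumerate(STANDARD_AA):
        for j, b in enumerate(STANDARD_AA):
            if i != j:
                K[i, j] = np.exp(m[a, b] / 2.0)
        K[i] /= K[i].sum()
    return STANDARD_AA, K


_KERNEL_ALPHABET, _KERNEL = blosum62_replacement_kernel()
_KERNEL_INDEX = {a: i for i, a in enumerate(_KERNEL_ALPHABET)}


def substitute(sequence: str, rate: float, protected: frozenset[int], rng: np.random.Generator) -> str:
    """Per-site substitution at ``rate`` (skipping protected sites) using the
    BLOSUM62-conditional kernel; a substitution always changes the residue."""
    out = list(sequence)
    for i, res in enumerate(out):
        if i in protected or rng.random() >= rate:
            continue
        row = _KERNEL[_KERNEL_INDEX[res]]
        out[i] = _KERNEL_ALPHABET[rng.choice(len(row), p=row)]
    return "".join(out)


def expected_pair_p_distance(ancestor: str, rate: float, protected: frozenset[int]) -> float:
    """Exact expected p-distance between two members of one class.

    Both members substitute independently from the ancestor at ``rate``; two
    sites differ when exactly one mutated, or both mutated to different
    targets.  Used as the closed-form oracle for the generator's divergence.
    """
    n = len(ancestor)
    total = 0.0
    for i, res in enumerate(ancestor):
        if i in protected:
            continue
        row = _KERNEL[_KERNEL_INDEX[res]]
        p_same_target = float((row ** 2).sum())
        total += 2 * rate * (1 - rate) + rate * rate * (1 - p_same_target)
    return total / n


@dataclass
class GenerationInfo:
    """Ground truth of one generated family set (for oracles and audits)."""

    root: str
    class_ancestors: dict[GeneClass, str]
    protected: frozenset[int]
    region_spans: dict[RegionTag, tuple[int, int]]
    signatures: dict[GeneClass, str]


def _region_spans(region_lengths: dict[RegionTag, int]) -> dict[RegionTag, tuple[int, int]]:
    spans = {}
    offset = 0
    for tag in DOMAIN_ORDER:
        length = region_lengths[tag]
        spans[tag] = (offset, offset + length)
        offset += length
    return spans


def _build_root(spec: SyntheticFamilySpec, rng: np.random.Generator) -> tuple[str, frozenset[int]]:
    """Root sequence plus the set of protected site indices."""
    lengths = spec.region_lengths
    spans = _region_spans(lengths)
    protected: set[int] = set()

    m_len = lengths[RegionTag.M]
    m_root = (M_CONSENSUS * (m_len // len(M_CONSENSUS) + 1))[:m_len]
    protected.update(range(min(M_PROTECTED, m_len)))

    i_root = "".join(rng.choice(list(_LINKER_POOL), size=lengths[RegionTag.I]))

    k_start = spans[RegionTag.K][0]
    k_chars = []
    for pos in range(lengths[RegionTag.K]):
        hp = pos % 7
        if spec.heptad_in_k and hp == 0:
            k_chars.append(rng.choice(list(_HYDROPHOBIC_A)))
            protected.add(k_start + pos)
        elif spec.heptad_in_k and hp == 3:
            k_chars.append(rng.choice(list(_HYDROPHOBIC_D)))
            protected.add(k_start + pos)
        else:
            k_chars.append(rng.choice(list(_POLAR_HEPTAD)))
    k_root = "".join(k_chars)

    c_root = "".join(rng.choice(list(_GENERAL_POOL), size=lengths[RegionTag.C_TERM]))
    # avoid accidental prolines breaking nothing in C; keep as drawn
    root = m_root + i_root + k_root + c_root
    c_start = spans[RegionTag.C_TERM][0]
    protected.update(range(c_start + SIGNATURE_START, c_start + SIGNATURE_START + SIGNATURE_LENGTH))
    return root, frozenset(protected)


def _class_signatures(rng: np.random.Generator) -> dict[GeneClass, str]:
    """Distinct class-specific 6-mers planted in the C domain."""
    signatures: dict[GeneClass, str] = {}
    seen: set[str] = set()
    for cls in CLASS_ORDER:
        while True:
            sig = "".join(rng.choice(list(STANDARD_AA), size=SIGNATURE_LENGTH))
            if sig not in seen:
                seen.add(sig)
                signatures[cls] = sig
                break
    return signatures


def generate_families(
    spec: SyntheticFamilySpec, *, return_info: bool = False
) -> LabeledDataset | tuple[LabeledDataset, GenerationInfo]:
    """Generate the eight-class synthetic family set with true annotations.

    One class ancestor per gene class is derived from a common root by
    applying per-region extra substitutions (and the class signature in C);
    members derive from their ancestor at the within-class rate.  Every
    generated sequence carries its true domain spans and is MIKC by
    construction.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    root, protected = _build_root(spec, rng)
    spans = _region_spans(spec.region_lengths)
    signatures = _class_signatures(rng)

    ancestors: dict[GeneClass, str] = {}
    for cls in CLASS_ORDER:
        anc = list(root)
        for region in DOMAIN_ORDER:
            start, end = spans[region]
            segment = "".join(anc[start:end])
            local_protected = frozenset(
                i - start for i in protected if start <= i < end
            )
            mutated = substitute(
                segment, spec.between_class_extra_rate[region], local_protected, rng
            )
            anc[start:end] = list(mutated)
        c_start = spans[RegionTag.C_TERM][0]
        sig_at = c_start + SIGNATURE_START
        anc[sig_at: sig_at + SIGNATURE_LENGTH] = list(signatures[cls])
        ancestors[cls] = "".join(anc)

    entries = []
    for cls in CLASS_ORDER:
        for member in range(spec.n_per_class):
            residues = substitute(
                ancestors[cls], spec.within_class_sub_rate, protected, rng
            )
            sid = f"{cls.value}_{member:03d}"
            seq = ProteinSequence(
                id=sid, residues=residues, description=f"synthetic class={cls.value}"
            )
            ann = DomainAnnotation(
                sequence_id=sid,
                spans=dict(spans),
                is_mikc=True,
                sequence_length=len(residues),
            )
            entries.append((seq, cls, ann))
    dataset = LabeledDataset(name=f"synthetic_seed{spec.seed}", entries=entries)
    if return_info:
        info = GenerationInfo(
            root=root,
            class_ancestors=ancestors,
            protected=protected,
            region_spans=spans,
            signatures=signatures,
        )
        return dataset, info
    return dataset


def truncate(
    seq: ProteinSequence,
    true_annotation: DomainAnnotation,
    keep: set[RegionTag] | Sequence[RegionTag],
    seed: int | None = None,
) -> tuple[ProteinSequence, DomainAnnotation]:
    """Cut a sequence down to a contiguous subset of its domains.

    ``keep`` must be contiguous in M < I < K < C order (e.g. {M}, {K, C} but
    not {M, C}).  The fragment annotation has the kept spans shifted to
    fragment coordinates.
    """
    keep_set = set(keep)
    if not keep_set:
        raise ValueError("keep must be non-empty")
    missing = keep_set - set(true_annotation.spans)
    if missing:
        raise ValueError(f"{seq.id}: regions not annotated: {sorted(r.label for r in missing)}")
    ordered = [t for t in DOMAIN_ORDER if t in keep_set]
    positions = [DOMAIN_ORDER.index(t) for t in ordered]
    if positions != list(range(positions[0], positions[0] + len(positions))):
        raise ValueError(f"keep set {[t.label for t in ordered]} is not contiguous")
    start = true_annotation.spans[ordered[0]][0]
    end = true_annotation.spans[ordered[-1]][1]
    fragment = ProteinSequence(
        id=f"{seq.id}|{''.join('MIKC'[DOMAIN_ORDER.index(t)] for t in ordered)}",
        residues=seq.residues[start:end],
        description=seq.description,
    )
    spans = {t: (s - start, e - start) for t, (s, e) in true_annotation.spans.items() if t in keep_set}
    ann = DomainAnnotation(
        sequence_id=fragment.id,
        spans=spans,
        is_mikc=RegionTag.M in spans,
        sequence_length=len(fragment.residues),
    )
    return fragment, ann


#: Domain-content keys for which fragment test sets are derived.
FRAGMENT_KEYS: tuple[tuple[str, tuple[RegionTag, ...]], ...] = (
    ("M", (RegionTag.M,)),
    ("MI", (RegionTag.M, RegionTag.I)),
    ("MIK", (RegionTag.M, RegionTag.I, RegionTag.K)),
    ("MIKC", (RegionTag.M, RegionTag.I, RegionTag.K, RegionTag.C_TERM)),
    ("KC", (RegionTag.K, RegionTag.C_TERM)),
    ("C", (RegionTag.C_TERM,)),
)


@dataclass
class BenchmarkBundle:
    """Stratified train/test split plus per-domain-content fragment test sets."""

    train: LabeledDataset
    test: LabeledDataset
    fragment_sets: dict[str, LabeledDataset]
    spec: SyntheticFamilySpec


def benchmark_bundle(spec: SyntheticFamilySpec, test_fraction: float = 0.2) -> BenchmarkBundle:
    """Generate families and split them into the benchmark layout.

    The split is stratified per class (every class appears in the test set);
    each fragment test set truncates every full-length test sequence to one
    domain-content key.  Deterministic per seed.
    """
    dataset = generate_families(spec)
    rng = np.random.default_rng(spec.seed + 1)
    n_test = max(1, int(round(spec.n_per_class * test_fraction)))
    test_ids: set[str] = set()
    for cls in CLASS_ORDER:
        ids = [seq.id for seq, c, _ in dataset.entries if c is cls]
        chosen = rng.choice(len(ids), size=n_test, replace=False)
        test_ids.update(ids[i] for i in chosen)
    train = dataset.subset(
        (e[0].id for e in dataset.entries if e[0].id not in test_ids),
        name=f"{dataset.name}_train",
    )
    test = dataset.subset(test_ids, name=f"{dataset.name}_test")

    fragment_sets: dict[str, LabeledDataset] = {}
    for key, regions in FRAGMENT_KEYS:
        entries = []
        for seq, cls, ann in test.entries:
            frag, frag_ann = truncate(seq, ann, set(regions))
            entries.append((frag, cls, frag_ann))
        fragment_sets[key] = LabeledDataset(name=f"{dataset.name}_frag_{key}", entries=entries)
    return BenchmarkBundle(train=train, test=test, fragment_sets=fragment_sets, spec=spec)


def write_bundle(bundle: BenchmarkBundle, outdir: str | Path) -> None:
    """Write the bundle in the FASTA + TSV manifest dialect seqio reads."""
    from .seqio import write_labeled_dataset

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_labeled_dataset(bundle.train, outdir / "train.fasta", outdir / "train.tsv")
    write_labeled_dataset(bundle.test, outdir / "test.fasta", outdir / "test.tsv")
    for key, ds in bundle.fragment_sets.items():
        write_labeled_dataset(ds, outdir / f"test_{key}.fasta", outdir / f"test_{key}.tsv")
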