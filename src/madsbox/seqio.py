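"""Sequence and labeled-dataset I/O.

Defines the on-disk layout used throughout the package: multi-record FASTA
for sequences and a TSV manifest (``sequence_id``, ``class``, optional
``domains``) carrying class labels and optional domain spans.  The manifest
is the single source of class labels; FASTA headers are never parsed for
labels.

Coordinates are 0-based, half-open everywhere.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .domain_scan import DomainAnnotation, RegionTag

logger = logging.getLogger(__name__)

#: The 20 standard amino-acid one-letter codes.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Residue alphabet used internally: the 20 standard letters plus X.
ALPHABET = frozenset(STANDARD_AA) | {"X"}

# Ambiguity / non-standard codes mapped to X with a logged warning.
_AMBIGUOUS = frozenset("BZUJO*")


class SequenceFormatError(ValueError):
    """Raised on malformed FASTA/manifest input."""


class GeneClass(Enum):
    """The eight MADS-box gene classes of the extended ABCDE model.

    Member order is fixed and used for every feature-vector layout,
    confidence-vector layout and argmax tie-break in the package.
    """

    A = "A"
    B12 = "B12"
    B34 = "B34"
    BPI = "BPI"
    C = "C"
    D = "D"
    E = "E"
    AGL6 = "AGL6"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Fixed class order (list of GeneClass, in declaration order).
CLASS_ORDER: tuple[GeneClass, ...] = tuple(GeneClass)


def parse_gene_class(label: str) -> GeneClass:
    """Parse a class label, with an error listing the allowed labels."""
    try:
        return GeneClass(label)
    except ValueError:
        allowed = ", ".join(c.value for c in CLASS_ORDER)
        raise SequenceFormatError(
            f"unknown gene class {label!r}; allowed labels: {allowed}"
        ) from None


def normalize_residues(residues: str, *, where: str = "sequence") -> str:
    """Uppercase ``residues`` and map non-standard codes (B, Z, U, J, O, *) to X.

    Characters outside the amino-acid alphabet raise
    :class:`SequenceFormatError`.
    """
    up = residues.upper()
    out = []
    mapped = 0
    for ch in up:
        if ch in ALPHABET:
            out.append(ch)
        elif ch in _AMBIGUOUS:
            out.append("X")
            mapped += 1
        else:
            raise SequenceFormatError(
                f"invalid residue character {ch!r} in {where}"
            )
    if mapped:
        logger.warning(
            "%s: mapped %d non-standard residue(s) to X", where, mapped
        )
    return "".join(out)


@dataclass(frozen=True)
class ProteinSequence:
    """An identified amino-acid sequence (query or reference)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceFormatError("sequence id must be nonempty")
        if not self.residues:
            raise SequenceFormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise SequenceFormatError(
                f"sequence {self.id!r} contains characters outside the "
                f"alphabet: {sorted(bad)}; normalize first"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def subsequence(self, span: tuple[int, int], new_id: str | None = None) -> "ProteinSequence":
        start, end = span
        if not (0 <= start < end <= len(self.residues)):
            raise ValueError(f"span {span} out of bounds for {self.id!r}")
        return ProteinSequence(
            id=new_id or self.id,
            residues=self.residues[start:end],
            description=self.description,
        )


@dataclass
class LabeledDataset:
    """A named list of (sequence, class, optional annotation) entries."""

    name: str
    entries: list[tuple[ProteinSequence, GeneClass, Optional[DomainAnnotation]]] = field(
        default_factory=list
    )

    def __post_init__(self) -> None:
        ids = [seq.id for seq, _, _ in self.entries]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SequenceFormatError(f"duplicate sequence ids: {dup}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def sequences(self) -> list[ProteinSequence]:
        return [seq for seq, _, _ in self.entries]

    @property
    def labels(self) -> dict[str, GeneClass]:
        return {seq.id: cls for seq, cls, _ in self.entries}

    @property
    def annotations(self) -> dict[str, Optional[DomainAnnotation]]:
        return {seq.id: ann for seq, _, ann in self.entries}

    def class_counts(self) -> dict[GeneClass, int]:
        counts = {c: 0 for c in CLASS_ORDER}
        for _, cls, _ in self.entries:
            counts[cls] += 1
        return counts

    def subset(self, ids: Iterable[str], name: str | None = None) -> "LabeledDataset":
        keep = set(ids)
        return LabeledDataset(
            name=name or f"{self.name}_subset",
            entries=[e for e in self.entries if e[0].id in keep],
        )


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read a multi-record FASTA file into normalized protein sequences.

    The record id is the first whitespace-delimited token of the header;
    file order is preserved.  Lowercase residues are uppercased; ambiguity
    codes map to X; anything else is a format error naming the record index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if not rec.id:
            raise SequenceFormatError(f"record {idx}: empty FASTA header")
        raw = str(rec.seq)
        if not raw:
            raise SequenceFormatError(f"record {idx} ({rec.id!r}): empty sequence")
        try:
            residues = normalize_residues(raw, where=f"record {idx} ({rec.id!r})")
        except SequenceFormatError as exc:
            raise SequenceFormatError(f"record {idx}: {exc}") from None
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(ProteinSequence(id=rec.id, residues=residues, description=desc))
    return records


def write_fasta(seqs: Iterable[ProteinSequence], path: str | Path, *, width: int = 60) -> None:
    """Write sequences as UTF-8, LF-terminated, wrapped FASTA."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description)
        for s in seqs
    ]
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def _parse_spans(text: str, seq_id: str, seq_len: int) -> DomainAnnotation:
    """Parse a manifest ``domains`` field like ``M:0-57;K:87-157``."""
    letter_to_tag = {"M": RegionTag.M, "I": RegionTag.I, "K": RegionTag.K, "C": RegionTag.C_TERM}
    spans: dict[RegionTag, tuple[int, int]] = {}
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        try:
            region, rng = part.split(":")
            start_s, end_s = rng.split("-")
            start, end = int(start_s), int(end_s)
        except ValueError:
            raise SequenceFormatError(
                f"{seq_id}: malformed domain span {part!r} (expected REGION:start-end)"
            ) from None
        if region not in letter_to_tag:
            raise SequenceFormatError(
                f"{seq_id}: unknown region {region!r} (allowed: M, I, K, C)"
            )
        spans[letter_to_tag[region]] = (start, end)
    return DomainAnnotation(
        sequence_id=seq_id,
        spans=spans,
        is_mikc=RegionTag.M in spans,
        sequence_length=seq_len,
    )


def load_labeled_dataset(
    fasta_path: str | Path,
    manifest_path: str | Path,
    *,
    name: str | None = None,
) -> LabeledDataset:
    """Join a FASTA file with its TSV manifest into a labeled dataset.

    The manifest must have a header row with columns ``sequence_id`` and
    ``class``; an optional ``domains`` column holds semicolon-separated
    0-based half-open spans (``M:0-57;I:57-87``).  Every manifest row must
    join to a FASTA record; FASTA records absent from the manifest are
    reported (logged) and dropped.
    """
    seqs = {s.id: s for s in read_fasta(fasta_path)}
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(manifest_path)
    entries: list[tuple[ProteinSequence, GeneClass, Optional[DomainAnnotation]]] = []
    with manifest_path.open(encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"sequence_id", "class"} <= set(reader.fieldnames):
            raise SequenceFormatError(
                f"{manifest_path}: manifest needs 'sequence_id' and 'class' columns"
            )
        seen = set()
        for row in reader:
            sid = row["sequence_id"].strip()
            if sid in seen:
                raise SequenceFormatError(f"duplicate manifest row for {sid!r}")
            seen.add(sid)
            if sid not in seqs:
                raise SequenceFormatError(
                    f"manifest id {sid!r} absent from FASTA {fasta_path}"
                )
            cls = parse_gene_class(row["class"].strip())
            ann: Optional[DomainAnnotation] = None
            domains = (row.get("domains") or "").strip()
            if domains:
                ann = _parse_spans(domains, sid, len(seqs[sid]))
            entries.append((seqs[sid], cls, ann))
    unjoined = sorted(set(seqs) - {e[0].id for e in entries})
    if unjoined:
        logger.warning(
            "%d FASTA record(s) not in manifest (dropped): %s",
            len(unjoined), ", ".join(unjoined[:10]),
        )
    return LabeledDataset(name=name or Path(fasta_path).stem, entries=entries)


def write_labeled_dataset(dataset: LabeledDataset, fasta_path: str | Path, manifest_path: str | Path) -> None:
    """Write a dataset in the same FASTA + TSV manifest dialect read back by
    :func:`load_labeled_dataset`."""
    write_fasta(dataset.sequences, fasta_path)
    tag_to_letter = {RegionTag.M: "M", RegionTag.I: "I", RegionTag.K: "K", RegionTag.C_TERM: "C"}
    with Path(manifest_path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("sequence_id\tclass\tdomains\n")
        for seq, cls, ann in dataset.entries:
            domains = ""
            if ann is not None:
                domains = ";".join(
                    f"{tag_to_letter[t]}:{s}-{e}"
                    for t, (s, e) in sorted(ann.spans.items(), key=lambda kv: kv[0].order)
                )
            fh.write(f"{seq.id}\t{cls.value}\t{domains}\n")
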