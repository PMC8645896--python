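"""Reading, validating, curating and writing peptide sequence data.

Sequences are plain FASTA over the 20-letter standard amino-acid alphabet.
The ambiguity / non-natural codes B, J, O, U, X and Z are never valid:
records containing them are either rejected (strict parsing) or tagged so
:func:`curate` can drop and count them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tables import ALPHABET

_VALID = set(ALPHABET)

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class Peptide:
    """A named peptide over the standard 20-letter alphabet.

    ``invalid_reason`` is only ever set by non-strict parsing; a peptide
    constructed directly must be valid.
    """

    id: str
    seq: str
    description: str = ""
    invalid_reason: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("peptide id must be non-empty")
        if not self.seq:
            raise ValueError(f"peptide {self.id!r}: empty sequence")
        if self.invalid_reason is None:
            bad = _first_invalid(self.seq)
            if bad is not None:
                pos, ch = bad
                raise ValueError(
                    f"peptide {self.id!r}: invalid residue {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def is_valid(self) -> bool:
        return self.invalid_reason is None


def _first_invalid(seq: str) -> tuple[int, str] | None:
    """1-based position and character of the first off-alphabet residue."""
    for i, ch in enumerate(seq, start=1):
        if ch not in _VALID:
            return i, ch
    return None


@dataclass(frozen=True)
class CurationConfig:
    """Length, alphabet and uniqueness rules applied by :func:`curate`."""

    min_len: int = 10
    max_len: int = 60
    drop_nonstandard: bool = True
    deduplicate: bool = True

    def __post_init__(self):
        if not (1 <= self.min_len <= self.max_len):
            raise ValueError("require 1 <= min_len <= max_len")


@dataclass
class LabeledDataset:
    """Peptides paired with binary class labels (positive / negative)."""

    records: list[tuple[Peptide, str]]
    name: str = "dataset"

    def __post_init__(self):
        seen: set[str] = set()
        for pep, label in self.records:
            if label not in (POSITIVE, NEGATIVE):
                raise ValueError(f"bad label {label!r} for {pep.id!r}")
            if pep.id in seen:
                raise ValueError(f"duplicate id {pep.id!r} in dataset")
            seen.add(pep.id)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def peptides(self) -> list[Peptide]:
        return [p for p, _ in self.records]

    @property
    def labels(self) -> list[str]:
        return [l for _, l in self.records]

    def subset(self, ids: Iterable[str], name: str | None = None) -> "LabeledDataset":
        wanted = set(ids)
        recs = [(p, l) for p, l in self.records if p.id in wanted]
        return LabeledDataset(recs, name=name or self.name)

    def class_counts(self) -> dict[str, int]:
        counts = {POSITIVE: 0, NEGATIVE: 0}
        for _, l in self.records:
            counts[l] += 1
        return counts


def read_fasta(path: str | Path, strict: bool = True) -> list[Peptide]:
    """Parse a FASTA file into peptides, uppercasing the sequence body.

    With ``strict=True`` any off-alphabet residue, duplicate header id or
    empty sequence raises; with ``strict=False`` offending records are
    returned tagged with ``invalid_reason`` so that :func:`curate` can
    filter and count them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")

    peptides: list[Peptide] = []
    seen_ids: set[str] = set()
    for rec in records:
        seq = str(rec.seq).upper()
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        if rec.id in seen_ids:
            if strict:
                raise ValueError(f"{path}: duplicate header id {rec.id!r}")
            peptides.append(
                Peptide(rec.id, seq or "X", desc, invalid_reason="duplicate id")
            )
            continue
        seen_ids.add(rec.id)
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = _first_invalid(seq)
        if bad is not None:
            pos, ch = bad
            if strict:
                raise ValueError(
                    f"{path}: record {rec.id!r} has invalid residue {ch!r} "
                    f"at position {pos}"
                )
            peptides.append(
                Peptide(rec.id, seq, desc,
                        invalid_reason=f"invalid residue {ch!r} at position {pos}")
            )
        else:
            peptides.append(Peptide(rec.id, seq, desc))
    return peptides


def write_fasta(records: Sequence[Peptide], path: str | Path, wrap: int = 60) -> None:
    """Write peptides as FASTA, wrapping sequence lines at ``wrap`` columns."""
    path = Path(path)
    seqrecords = [
        SeqRecord(Seq(p.seq), id=p.id, description=p.description)
        for p in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seqrecords)


def curate(
    records: Sequence[Peptide], cfg: CurationConfig = CurationConfig()
) -> tuple[list[Peptide], dict[str, int]]:
    """Apply length / alphabet / uniqueness rules, returning kept peptides
    and a per-rule drop-count report.

    Rule precedence per record: nonstandard alphabet, then length bounds,
    then duplicate sequence (first occurrence kept).  The report's counts
    sum to ``len(records) - len(kept)``.
    """
    report = {"nonstandard": 0, "too_short": 0, "too_long": 0, "duplicate": 0}
    kept: list[Peptide] = []
    seen_seqs: set[str] = set()
    for pep in records:
        if not pep.is_valid:
            if cfg.drop_nonstandard:
                report["nonstandard"] += 1
                continue
            raise ValueError(
                f"record {pep.id!r} is invalid ({pep.invalid_reason}) and "
                "drop_nonstandard is off"
            )
        if len(pep) < cfg.min_len:
            report["too_short"] += 1
            continue
        if len(pep) > cfg.max_len:
            report["too_long"] += 1
            continue
        if cfg.deduplicate:
            if pep.seq in seen_seqs:
                report["duplicate"] += 1
                continue
            seen_seqs.add(pep.seq)
        kept.append(pep)
    return kept, report


def load_labeled(
    pos_path: str | Path,
    neg_path: str | Path,
    name: str = "dataset",
    strict: bool = True,
) -> LabeledDataset:
    """Build a labeled dataset from a positive and a negative FASTA file.

    Ids must be unique across the two files; the first file's records are
    labeled positive.
    """
    pos = read_fasta(pos_path, strict=strict)
    neg = read_fasta(neg_path, strict=strict)
    pos_ids = {p.id for p in pos}
    clash = pos_ids & {p.id for p in neg}
    if clash:
        raise ValueError(f"ids present in both files: {sorted(clash)[:5]}")
    records = [(p, POSITIVE) for p in pos] + [(p, NEGATIVE) for p in neg]
    invalid = [p.id for p, _ in records if not p.is_valid]
    if invalid:
        warnings.warn(f"{len(invalid)} invalid records tagged for curation")
    return LabeledDataset(records, name=name)


def curate_dataset(
    ds: LabeledDataset, cfg: CurationConfig = CurationConfig()
) -> tuple[LabeledDataset, dict[str, dict[str, int]]]:
    """Curate each class of a labeled dataset independently."""
    reports: dict[str, dict[str, int]] = {}
    kept_records: list[tuple[Peptide, str]] = []
    for label in (POSITIVE, NEGATIVE):
        class_peps = [p for p, l in ds.records if l == label]
        kept, rep = curate(class_peps, cfg)
        reports[label] = rep
        kept_records.extend((p, label) for p in kept)
    return LabeledDataset(kept_records, name=ds.name), reports
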