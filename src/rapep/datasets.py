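"""Peptide dataset containers, I/O, cleaning and splitting.

Datasets are ordered collections of short peptides (typically 9-20 residues)
labelled as disease-inducing (positive) or non-inducing (negative). FASTA
headers encode the label as a ``|1`` / ``|0`` suffix token; CSV files use
``id,sequence[,label][,count]`` columns.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"

_LABEL_TO_STR = {1: POSITIVE, 0: NEGATIVE}
_STR_TO_INT = {POSITIVE: 1, NEGATIVE: 0, "1": 1, "0": 0, "pos": 1, "neg": 0}


class DatasetError(ValueError):
    """Malformed or unusable peptide dataset."""


class DegenerateDatasetError(DatasetError):
    """Cleaning removed every peptide of one class."""


@dataclass(frozen=True)
class Peptide:
    """A single peptide record.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    sequence : str
        Uppercase sequence over the 20 standard residues.
    label : str
        One of ``"positive"``, ``"negative"``, ``"unknown"``.
    count : int, optional
        Occurrence/assay count annotation, when available.
    """

    id: str
    sequence: str
    label: str = UNKNOWN
    count: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DatasetError(f"peptide {self.id!r}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise DatasetError(
                f"peptide {self.id!r}: invalid residues {sorted(bad)}"
            )
        if self.label not in (POSITIVE, NEGATIVE, UNKNOWN):
            raise DatasetError(f"peptide {self.id!r}: bad label {self.label!r}")
        if self.count is not None and self.count < 0:
            raise DatasetError(f"peptide {self.id!r}: negative count")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RemovalRecord:
    id: str
    sequence: str
    reason: str


@dataclass
class PeptideDataset:
    """Ordered collection of peptides with free-text provenance."""

    peptides: list[Peptide] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [p.id for p in self.peptides]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DatasetError(f"duplicate peptide ids: {dup[:5]}")

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self) -> Iterator[Peptide]:
        return iter(self.peptides)

    def __getitem__(self, i: int) -> Peptide:
        return self.peptides[i]

    @property
    def sequences(self) -> list[str]:
        return [p.sequence for p in self.peptides]

    @property
    def labels(self) -> np.ndarray:
        """Numeric labels (1 positive, 0 negative, -1 unknown)."""
        return np.array(
            [{POSITIVE: 1, NEGATIVE: 0}.get(p.label, -1) for p in self.peptides]
        )

    def subset(self, label: str) -> "PeptideDataset":
        return PeptideDataset(
            [p for p in self.peptides if p.label == label],
            provenance=f"{self.provenance} [{label}]".strip(),
        )

    @property
    def positives(self) -> "PeptideDataset":
        return self.subset(POSITIVE)

    @property
    def negatives(self) -> "PeptideDataset":
        return self.subset(NEGATIVE)

    # ------------------------------------------------------------------ I/O
    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for p in self.peptides:
                suffix = ""
                if p.label in (_STR_TO_INT):
                    suffix = f"|{_STR_TO_INT[p.label]}"
                fh.write(f">{p.id}{suffix}\n{p.sequence}\n")

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "sequence", "label", "count"])
            for p in self.peptides:
                lab = _STR_TO_INT.get(p.label, "")
                writer.writerow(
                    [p.id, p.sequence, lab, "" if p.count is None else p.count]
                )


def _parse_label(token: str) -> str:
    token = token.strip().lower()
    if token in ("", "unknown", "none"):
        return UNKNOWN
    if token in _STR_TO_INT:
        return _LABEL_TO_STR[_STR_TO_INT[token]]
    raise DatasetError(f"unrecognized label {token!r}")


def read_peptides(
    path: str | Path, format: str | None = None, strict: bool = False
) -> PeptideDataset:
    """Read a peptide dataset from FASTA or CSV.

    Records whose sequence contains characters outside the 20-residue
    alphabet are rejected; their ids are reported in a :class:`UserWarning`
    (or raised when ``strict=True``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "fasta"
    if format not in ("fasta", "csv"):
        raise ValueError(f"unknown format {format!r}")

    raw: list[tuple[str, str, str, int | None]] = []
    if format == "fasta":
        from Bio import SeqIO

        for rec in SeqIO.parse(str(path), "fasta"):
            if not rec.id:
                raise DatasetError(f"{path}: FASTA record with empty header")
            name, _, lab = rec.id.rpartition("|")
            if name and lab in ("0", "1"):
                raw.append((name, str(rec.seq).upper(), _parse_label(lab), None))
            else:
                raw.append((rec.id, str(rec.seq).upper(), UNKNOWN, None))
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or "sequence" not in reader.fieldnames:
                raise DatasetError(f"{path}: CSV must have a 'sequence' column")
            for i, row in enumerate(reader):
                pid = (row.get("id") or f"pep{i + 1}").strip()
                count = row.get("count")
                count = int(count) if count not in (None, "") else None
                raw.append(
                    (
                        pid,
                        row["sequence"].strip().upper(),
                        _parse_label(row.get("label") or ""),
                        count,
                    )
                )

    peptides, rejected = [], []
    for pid, seq, lab, count in raw:
        if not seq or set(seq) - _AA_SET:
            rejected.append(pid)
        else:
            peptides.append(Peptide(pid, seq, lab, count))
    if rejected:
        msg = f"{path}: rejected {len(rejected)} record(s) with invalid residues: {rejected}"
        if strict:
            raise DatasetError(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    if not peptides:
        raise DatasetError(f"{path}: no valid peptide records")
    return PeptideDataset(peptides, provenance=str(path))


def clean_dataset(
    raw: PeptideDataset,
    min_len: int = 9,
    max_len: int = 20,
    min_count: int | None = None,
) -> tuple[PeptideDataset, list[RemovalRecord]]:
    """Apply the standard preprocessing filters.

    In order: collapse duplicate sequences within each class, drop negative
    sequences identical to a positive sequence, drop sequences with length
    outside ``[min_len, max_len]``, and (when ``min_count`` is set) drop
    positives whose occurrence count is below the threshold.

    Returns the cleaned dataset and a removal report (one record per
    removed peptide, with its reason).

    Raises
    ------
    DegenerateDatasetError
        If a previously non-empty class loses all its members.
    """
    report: list[RemovalRecord] = []
    seen: dict[tuple[str, str], str] = {}
    kept: list[Peptide] = []
    for p in raw:
        key = (p.label, p.sequence)
        if key in seen:
            report.append(RemovalRecord(p.id, p.sequence, "duplicate-within-class"))
        else:
            seen[key] = p.id
            kept.append(p)

    positive_seqs = {p.sequence for p in kept if p.label == POSITIVE}
    stage2 = []
    for p in kept:
        if p.label == NEGATIVE and p.sequence in positive_seqs:
            report.append(RemovalRecord(p.id, p.sequence, "cross-class-duplicate"))
        else:
            stage2.append(p)

    stage3 = []
    for p in stage2:
        if len(p) < min_len:
            report.append(RemovalRecord(p.id, p.sequence, f"length<{min_len}"))
        elif len(p) > max_len:
            report.append(RemovalRecord(p.id, p.sequence, f"length>{max_len}"))
        else:
            stage3.append(p)

    final = []
    for p in stage3:
        if (
            min_count is not None
            and p.label == POSITIVE
            and p.count is not None
            and p.count < min_count
        ):
            report.append(RemovalRecord(p.id, p.sequence, f"count<{min_count}"))
        else:
            final.append(p)

    for label in (POSITIVE, NEGATIVE):
        had = any(p.label == label for p in raw)
        has = any(p.label == label for p in final)
        if had and not has:
            raise DegenerateDatasetError(
                f"cleaning removed every {label} peptide"
            )
    return PeptideDataset(final, provenance=f"{raw.provenance} [cleaned]".strip()), report


def write_removal_report(report: Sequence[RemovalRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsequence\treason\n")
        for r in report:
            fh.write(f"{r.id}\t{r.sequence}\t{r.reason}\n")


def split_dataset(
    data: PeptideDataset, train_fraction: float = 0.8, seed: int = 0
) -> tuple[PeptideDataset, PeptideDataset]:
    """Stratified train/validation split.

    The validation side receives ``floor((1 - train_fraction) * n)`` peptides
    of each class; the split is deterministic for a given seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    pos = [p for p in data if p.label == POSITIVE]
    neg = [p for p in data if p.label == NEGATIVE]
    if not pos or not neg:
        raise DatasetError("split requires both classes to be non-empty")
    rng = np.random.default_rng(seed)
    train: list[Peptide] = []
    val: list[Peptide] = []
    for group in (pos, neg):
        # floor of the exact validation fraction, guarded against FP noise
        n_val = int(np.floor(np.round((1.0 - train_fraction) * len(group), 9)))
        order = rng.permutation(len(group))
        val_idx = set(order[:n_val].tolist())
        for i, p in enumerate(group):
            (val if i in val_idx else train).append(p)
    return (
        PeptideDataset(train, provenance=f"{data.provenance} [train]".strip()),
        PeptideDataset(val, provenance=f"{data.provenance} [validation]".strip()),
    )


def from_sequences(
    positives: Iterable[str],
    negatives: Iterable[str] = (),
    unknowns: Iterable[str] = (),
    prefix: str = "pep",
) -> PeptideDataset:
    """Build a dataset from plain sequence iterables (ids auto-assigned)."""
    peptides = []
    i = 0
    for seqs, lab in ((positives, POSITIVE), (negatives, NEGATIVE), (unknowns, UNKNOWN)):
        for s in seqs:
            i += 1
            peptides.append(Peptide(f"{prefix}{i}", s.upper(), lab))
    return PeptideDataset(peptides)
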