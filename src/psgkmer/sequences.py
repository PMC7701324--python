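"""Reading, validating and splitting labeled fixed-length RNA windows.

The datasets handled here are collections of fixed-length nucleotide
windows (default 41 nt) centred on a candidate cytosine; the positive
class carries a 5-hydroxymethylcytosine (5hmC) mark at that centre.
Sequences are canonicalized to the RNA alphabet {A, C, G, U}; thymine on
input is silently read as uracil so DNA-alphabet files work unchanged.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

from .patterns import ALPHABET

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 41

_VALID_INPUT = set("ACGUTacgut")
_HEADER_LABEL = re.compile(r"\|label=([01])$")


class ValidationError(ValueError):
    """A sequence record violated the dataset contract."""


def canonicalize(residues: str) -> str:
    """Canonicalize a raw residue string to uppercase {A,C,G,U}.

    T (thymine) is mapped to U.  Any other character raises
    :class:`ValidationError` naming the first offending position (1-based).
    """
    if not residues:
        raise ValidationError("empty residue string")
    for i, ch in enumerate(residues):
        if ch not in _VALID_INPUT:
            raise ValidationError(
                f"invalid residue {ch!r} at position {i + 1}"
            )
    return residues.upper().replace("T", "U")


@dataclass(frozen=True)
class SequenceRecord:
    """One fixed-length window: an id, canonical residues, optional label
    (1 = modified central cytosine, 0 = unmodified)."""

    id: str
    residues: str
    label: int | None = None

    def __post_init__(self) -> None:
        if self.label not in (None, 0, 1):
            raise ValidationError(f"label must be 0/1/None, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def central_residue(self) -> str:
        """Residue at the central 1-based position (L+1)//2."""
        return self.residues[(len(self.residues) - 1) // 2]


@dataclass
class Dataset:
    """An ordered collection of equal-length sequence records."""

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            raise ValidationError(f"mixed record lengths: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValidationError(f"duplicate record id {dup!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> SequenceRecord:
        return self.records[i]

    @property
    def L(self) -> int | None:
        """Common window length, or None for an empty dataset."""
        return len(self.records[0]) if self.records else None

    @property
    def labels(self) -> np.ndarray | None:
        """Label vector, or None when any record is unlabeled."""
        if any(r.label is None for r in self.records) or not self.records:
            return None
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def label_counts(self) -> tuple[int, int]:
        """(n_positive, n_negative) over labeled records."""
        pos = sum(1 for r in self.records if r.label == 1)
        neg = sum(1 for r in self.records if r.label == 0)
        return pos, neg

    def subset(self, indices: Sequence[int]) -> "Dataset":
        return Dataset([self.records[i] for i in indices])


def _validate_record(
    rec: SequenceRecord, L: int | None, strict: bool, central_c: str
) -> SequenceRecord | None:
    if L is not None and len(rec) != L:
        if strict:
            raise ValidationError(
                f"record {rec.id!r} has length {len(rec)}, expected {L}"
            )
        logger.warning("dropping record %s: length %d != %d", rec.id, len(rec), L)
        return None
    if rec.central_residue != "C":
        msg = (
            f"record {rec.id!r} has {rec.central_residue!r} (not C) at the "
            f"central position {(len(rec) + 1) // 2}"
        )
        if central_c == "error":
            raise ValidationError(msg)
        if central_c == "warn":
            logger.warning(msg)
    return rec


def read_labels_tsv(path: str | Path) -> dict[str, int]:
    """Read a two-column (id, 0/1) TSV label map."""
    labels: dict[str, int] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise ValidationError(f"label row {row!r} needs two columns")
            rid, raw = row[0], row[1].strip()
            if raw not in ("0", "1"):
                raise ValidationError(f"label for {rid!r} must be 0/1, got {raw!r}")
            if rid in labels:
                raise ValidationError(f"duplicate label for id {rid!r}")
            labels[rid] = int(raw)
    return labels


def write_labels_tsv(dataset: Dataset, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for rec in dataset:
            if rec.label is None:
                raise ValidationError(f"record {rec.id!r} has no label to write")
            writer.writerow([rec.id, rec.label])


def read_fasta(
    path: str | Path,
    labels: str | Path | dict[str, int] | None = None,
    *,
    L: int | None = None,
    strict: bool = True,
    central_c: str = "warn",
    require_labels: bool = False,
) -> Dataset:
    """Read a FASTA file (optionally with labels) into a :class:`Dataset`.

    Parameters
    ----------
    labels:
        A label-map source: a two-column TSV path or a dict ``id -> 0/1``.
        Labels may alternatively be encoded in headers as ``|label=0/1``;
        a disagreement between the two sources is an error.
    L:
        Expected window length.  When None, inferred from the first record.
    strict:
        In strict mode a wrong-length or non-alphabet record raises
        :class:`ValidationError`; in lenient mode it is dropped with a warning.
    central_c:
        "warn" (default), "error" or "ignore" — what to do when the central
        residue is not C.
    """
    if central_c not in ("warn", "error", "ignore"):
        raise ValueError(f"central_c must be warn/error/ignore, got {central_c!r}")
    label_map: dict[str, int] | None
    if labels is None:
        label_map = None
    elif isinstance(labels, dict):
        label_map = dict(labels)
    else:
        label_map = read_labels_tsv(labels)

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for seqrec in SeqIO.parse(str(path), "fasta"):
        rid = seqrec.id
        header_label: int | None = None
        m = _HEADER_LABEL.search(seqrec.description)
        if m:
            header_label = int(m.group(1))
            rid = _HEADER_LABEL.sub("", rid)
        if rid in seen:
            raise ValidationError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        try:
            residues = canonicalize(str(seqrec.seq))
        except ValidationError as err:
            if strict:
                raise ValidationError(f"record {rid!r}: {err}") from None
            logger.warning("dropping record %s: %s", rid, err)
            continue
        label = header_label
        if label_map is not None and rid in label_map:
            if header_label is not None and header_label != label_map[rid]:
                raise ValidationError(
                    f"record {rid!r}: header label {header_label} conflicts "
                    f"with TSV label {label_map[rid]}"
                )
            label = label_map[rid]
        elif label_map is not None and require_labels:
            raise ValidationError(f"record {rid!r} has no label in the label map")
        rec = SequenceRecord(rid, residues, label)
        if L is None:
            L = len(rec)
        rec2 = _validate_record(rec, L, strict, central_c)
        if rec2 is not None:
            records.append(rec2)
    if not records:
        logger.warning("no records read from %s", path)
    return Dataset(records)


def write_fasta(
    dataset: Dataset, path: str | Path, *, label_in_header: bool = False
) -> None:
    """Write canonical records as FASTA; optionally append ``|label=``."""
    with open(path, "w") as fh:
        for rec in dataset:
            header = rec.id
            if label_in_header and rec.label is not None:
                header = f"{rec.id}|label={rec.label}"
            fh.write(f">{header}\n{rec.residues}\n")


def stratified_holdout(
    dataset: Dataset, fraction: float, seed: int
) -> tuple[Dataset, Dataset]:
    """Split off a label-stratified holdout of ``round(fraction * n)`` records.

    Class proportions in the holdout match the dataset to within one sample
    per class (largest-remainder allocation).  Record order within each
    split follows the original dataset.  Reproducible for a fixed seed.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    y = dataset.labels
    if y is None:
        raise ValidationError("stratified split requires labels on every record")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError("stratified split requires both classes present")

    n = len(dataset)
    n_test = round(fraction * n)
    ideals = {c: fraction * int((y == c).sum()) for c in classes}
    base = {c: int(np.floor(v)) for c, v in ideals.items()}
    short = n_test - sum(base.values())
    # hand leftover slots to the classes with the largest fractional remainder
    order = sorted(classes, key=lambda c: ideals[c] - base[c], reverse=True)
    for c in order[:short]:
        base[c] += 1

    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for c in classes:
        members = np.flatnonzero(y == c)
        chosen = rng.choice(members, size=base[c], replace=False)
        test_idx.extend(int(i) for i in chosen)
    test_set = set(test_idx)
    train = dataset.subset([i for i in range(n) if i not in test_set])
    test = dataset.subset(sorted(test_set))
    return train, test
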