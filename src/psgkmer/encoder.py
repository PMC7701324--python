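"""Descriptor enumeration and sequence-to-feature-matrix encoding.

Every window length L induces a fixed, canonically ordered descriptor
space.  The binary part consists of one indicator per (pattern, start)
pair across ten feature types:

* FT1-FT3 — ungapped position-specific k-mers (k = 1, 2, 3);
* FT4-FT6 — monomer (g) dimer patterns, g = 1, 2, 3;
* FT7-FT9 — dimer (g) monomer patterns, g = 1, 2, 3;
* FT10    — monomer (1) monomer (1) monomer patterns.

FT11 is the GC-content percentage and is always the last column.  For
L = 41 the space has 19,876 binary indicators plus GC = 19,877 columns.

Within a feature type the canonical column order is pattern-major
(patterns in their canonical enumeration order) and start-minor, so a
pattern's indicator string occupies a contiguous block of columns.
Because each feature type's patterns enumerate all fixed-nucleotide
combinations of one template shape, exactly one pattern per (type,
start) matches any window: an encoded 41-nt row has exactly 379 ones in
its binary part.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy import sparse

from .patterns import (
    ALPHABET,
    GappedPattern,
    Mode,
    enumerate_mode_patterns,
    match,
)
from .sequences import Dataset

logger = logging.getLogger(__name__)

GC_FEATURE_TYPE = "FT11"
GC_NAME = "FT11:GC"

#: feature type -> (mode, gap configuration); order defines the canonical
#: column layout.  FT11 (GC) is appended after all binary types.
FEATURE_TYPES: tuple[tuple[str, Mode, tuple[int, ...]], ...] = (
    ("FT1", Mode.PSM, ()),
    ("FT2", Mode.PSD, ()),
    ("FT3", Mode.PST, ()),
    ("FT4", Mode.PSMGD, (1,)),
    ("FT5", Mode.PSMGD, (2,)),
    ("FT6", Mode.PSMGD, (3,)),
    ("FT7", Mode.PSDGM, (1,)),
    ("FT8", Mode.PSDGM, (2,)),
    ("FT9", Mode.PSDGM, (3,)),
    ("FT10", Mode.PSMGMGM, (1, 1)),
)

_MIN_L = 6  # the longest template (6 nt) must fit at least once

_CODE = np.full(128, -1, dtype=np.int64)
for _i, _ch in enumerate(ALPHABET):
    _CODE[ord(_ch)] = _i


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identity of one feature-space column.

    Binary descriptors pair a pattern with a 1-based window start; the GC
    descriptor has neither.  ``name`` follows the grammar
    ``<FT>:<template>@<start>-<end>`` (or ``FT11:GC``) and uniquely
    determines the column.
    """

    feature_type: str
    pattern: GappedPattern | None
    start: int | None
    name: str
    index: int

    @property
    def end(self) -> int | None:
        """1-based inclusive end position of the matched window."""
        if self.pattern is None or self.start is None:
            return None
        return self.start + self.pattern.span - 1


def _type_patterns(feature_type: str) -> tuple[GappedPattern, ...]:
    for ft, mode, gaps in FEATURE_TYPES:
        if ft == feature_type:
            return tuple(
                p for p in enumerate_mode_patterns(mode) if p.gap_lengths == gaps
            )
    raise KeyError(feature_type)


@lru_cache(maxsize=8)
def enumerate_descriptors(L: int) -> tuple[FeatureDescriptor, ...]:
    """The canonical descriptor list for window length ``L``.

    Raises ``ValueError`` for L < 6, where the longest template no longer
    fits.  For L = 41 this yields 19,877 descriptors (19,876 binary + GC).
    """
    if L < _MIN_L:
        raise ValueError(f"window length must be >= {_MIN_L}, got {L}")
    out: list[FeatureDescriptor] = []
    idx = 0
    for ft, mode, gaps in FEATURE_TYPES:
        patterns = tuple(
            p for p in enumerate_mode_patterns(mode) if p.gap_lengths == gaps
        )
        span = patterns[0].span
        n_windows = L - span + 1
        for pat in patterns:
            for start in range(1, n_windows + 1):
                name = f"{ft}:{pat.template}@{start}-{start + span - 1}"
                out.append(FeatureDescriptor(ft, pat, start, name, idx))
                idx += 1
    out.append(FeatureDescriptor(GC_FEATURE_TYPE, None, None, GC_NAME, idx))
    return tuple(out)


def descriptor_counts(L: int) -> dict[str, int]:
    """Number of descriptors per feature type at window length ``L``."""
    counts: dict[str, int] = {}
    for d in enumerate_descriptors(L):
        counts[d.feature_type] = counts.get(d.feature_type, 0) + 1
    return counts


def indicator_string(pattern: GappedPattern, residues: str) -> str:
    """Slide ``pattern`` along ``residues``; '1' per matching window.

    The result has one digit per admissible start, length
    ``len(residues) - M + 1``.
    """
    m = pattern.span
    if len(residues) < m:
        raise ValueError(
            f"sequence length {len(residues)} shorter than pattern span {m}"
        )
    return "".join(
        str(match(pattern, residues, start))
        for start in range(1, len(residues) - m + 2)
    )


def gc_content(residues: str) -> float:
    """GC percentage: 100 * (G + C) / (A + C + G + U)."""
    if not residues:
        raise ValueError("empty sequence")
    gc = residues.count("G") + residues.count("C")
    return 100.0 * gc / len(residues)


def _encode_codes(codes: np.ndarray, L: int) -> np.ndarray:
    """Column indices of the active binary descriptors for one sequence."""
    cols: list[np.ndarray] = []
    base = 0
    for ft, mode, gaps in FEATURE_TYPES:
        patterns = _type_patterns(ft)
        span = patterns[0].span
        offs = patterns[0].fixed_offsets
        n_windows = L - span + 1
        idx = np.arange(n_windows)
        ranks = np.zeros(n_windows, dtype=np.int64)
        for off in offs:
            # base-4 rank of the fixed residues = the matching pattern's
            # position in the canonical lexicographic enumeration
            ranks = ranks * 4 + codes[idx + off]
        cols.append(base + ranks * n_windows + idx)
        base += len(patterns) * n_windows
    return np.concatenate(cols)


class FeatureMatrix:
    """A samples x descriptors matrix in canonical column order.

    The binary indicators are held sparsely; the GC column (a percentage
    in [0, 100]) is the final column of the same matrix.
    """

    def __init__(
        self,
        values: sparse.csr_matrix,
        descriptors: tuple[FeatureDescriptor, ...] | list[FeatureDescriptor],
        sample_ids: list[str],
        labels: np.ndarray | None = None,
    ) -> None:
        descriptors = tuple(descriptors)
        if values.shape != (len(sample_ids), len(descriptors)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(sample_ids)} samples x {len(descriptors)} descriptors"
            )
        if labels is not None:
            labels = np.asarray(labels, dtype=int)
            if labels.shape != (len(sample_ids),):
                raise ValueError("label vector length mismatch")
        self.values = values.tocsr()
        self.descriptors = descriptors
        self.sample_ids = list(sample_ids)
        self.labels = labels
        self._name_to_index = {d.name: d.index for d in descriptors}

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.descriptors)

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def column_index(self, name: str) -> int:
        return self._name_to_index[name]

    def toarray(self) -> np.ndarray:
        return self.values.toarray()

    def select_columns(self, indices: np.ndarray | list[int]) -> "FeatureMatrix":
        """Restrict to a subset of columns; descriptors are re-indexed."""
        indices = np.asarray(indices, dtype=int)
        sub = self.values[:, indices]
        descs = tuple(
            FeatureDescriptor(
                d.feature_type, d.pattern, d.start, d.name, new_idx
            )
            for new_idx, d in enumerate(self.descriptors[i] for i in indices)
        )
        return FeatureMatrix(sub.tocsr(), descs, self.sample_ids, self.labels)

    def select_rows(self, indices: np.ndarray | list[int]) -> "FeatureMatrix":
        indices = np.asarray(indices, dtype=int)
        labels = self.labels[indices] if self.labels is not None else None
        return FeatureMatrix(
            self.values[indices].tocsr(),
            self.descriptors,
            [self.sample_ids[i] for i in indices],
            labels,
        )

    # -- text I/O ---------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Dense delimited export: one row per sample, named columns."""
        dense = self.toarray()
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["id", *self.names])
            for sid, row in zip(self.sample_ids, dense):
                writer.writerow([sid, *(_fmt(v) for v in row)])

    def to_triplets(self, path: str | Path) -> None:
        """Sparse export: (sample id, column name, value) triplets.

        A header line records the full column universe so zero columns and
        empty matrices round-trip.
        """
        coo = self.values.tocoo()
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["#samples", *self.sample_ids])
            writer.writerow(["#columns", *self.names])
            for r, c, v in zip(coo.row, coo.col, coo.data):
                writer.writerow([self.sample_ids[r], self.names[c], _fmt(v)])

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            names = header[1:]
            ids, rows = [], []
            for row in reader:
                ids.append(row[0])
                rows.append([float(v) for v in row[1:]])
        values = sparse.csr_matrix(
            np.array(rows, dtype=float).reshape(len(ids), len(names))
        )
        return cls(values, _descriptors_from_names(names), ids)

    @classmethod
    def from_triplets(cls, path: str | Path) -> "FeatureMatrix":
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            sample_row = next(reader)
            col_row = next(reader)
            if sample_row[0] != "#samples" or col_row[0] != "#columns":
                raise ValueError(f"{path} is not a triplet matrix export")
            ids = sample_row[1:]
            names = col_row[1:]
            row_of = {s: i for i, s in enumerate(ids)}
            col_of = {n: j for j, n in enumerate(names)}
            r, c, v = [], [], []
            for row in reader:
                r.append(row_of[row[0]])
                c.append(col_of[row[1]])
                v.append(float(row[2]))
        values = sparse.csr_matrix(
            (v, (r, c)), shape=(len(ids), len(names))
        )
        return cls(values, _descriptors_from_names(names), ids)


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def _descriptors_from_names(names: list[str]) -> tuple[FeatureDescriptor, ...]:
    from .patterns import parse_template

    out = []
    for idx, name in enumerate(names):
        if name == GC_NAME:
            out.append(FeatureDescriptor(GC_FEATURE_TYPE, None, None, name, idx))
            continue
        ft, rest = name.split(":", 1)
        template, pos = rest.split("@")
        start = int(pos.split("-")[0])
        out.append(
            FeatureDescriptor(ft, parse_template(template), start, name, idx)
        )
    return tuple(out)


def encode_dataset(
    dataset: Dataset, *, L: int | None = None, normalize_gc: bool = False
) -> FeatureMatrix:
    """Encode every record of a uniform-length dataset.

    Rows follow input order; columns follow the canonical descriptor order
    for the dataset's window length (overridable via ``L`` only for an
    empty dataset, which otherwise defaults to the 41-nt layout).
    ``normalize_gc`` rescales the GC column to [0, 1] for optimizer
    conditioning (off by default).
    """
    from .sequences import DEFAULT_WINDOW

    if dataset.L is not None:
        L = dataset.L
    elif L is None:
        L = DEFAULT_WINDOW
    descriptors = enumerate_descriptors(L)
    n_cols = len(descriptors)
    gc_col = n_cols - 1
    indptr = [0]
    indices: list[np.ndarray] = []
    data: list[np.ndarray] = []
    for rec in dataset:
        codes = _CODE[np.frombuffer(rec.residues.encode(), dtype=np.uint8)]
        cols = _encode_codes(codes, L)
        gc = gc_content(rec.residues)
        if normalize_gc:
            gc /= 100.0
        row_cols = np.concatenate([cols, [gc_col]])
        row_data = np.concatenate([np.ones(len(cols)), [gc]])
        if gc == 0.0:  # keep explicit-zero GC out of the sparse structure
            row_cols, row_data = row_cols[:-1], row_data[:-1]
        indices.append(row_cols)
        data.append(row_data)
        indptr.append(indptr[-1] + len(row_cols))
    values = sparse.csr_matrix(
        (
            np.concatenate(data) if data else np.empty(0),
            np.concatenate(indices) if indices else np.empty(0, dtype=int),
            np.array(indptr),
        ),
        shape=(len(dataset), n_cols),
    )
    logger.info(
        "encoded %d sequences into %d descriptor columns", len(dataset), n_cols
    )
    return FeatureMatrix(values, descriptors, dataset.ids, dataset.labels)
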