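"""Synthetic labeled sequence windows with planted position-specific motifs.

The generator emulates the shape of a balanced 5hmC benchmark: n
positive and n negative 41-nt windows over {A,C,G,U} with a cytosine
forced at the centre, residues drawn i.i.d. from a background
distribution.  Class signal is injected by *plants*: a gapped-pattern
template written at a fixed window start with class-conditional
probability (p_pos in positives, p_neg in negatives).  Only the fixed
positions of the template are overwritten — gap positions stay
background draws — so the planted signal is exactly the object the
position-specific gapped k-mer descriptors detect, and the expected
match rate of the planted descriptor is p + (1 - p) * b, where b is the
background chance of matching (product of the fixed residues' background
probabilities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .patterns import ALPHABET, GappedPattern, parse_template
from .sequences import Dataset, SequenceRecord

DEFAULT_BACKGROUND = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class Plant:
    """A template planted at a fixed 1-based start with class-conditional
    write probabilities."""

    template: str
    start: int
    p_pos: float
    p_neg: float

    @property
    def pattern(self) -> GappedPattern:
        return parse_template(self.template)

    @property
    def fixed_positions(self) -> dict[int, str]:
        """1-based sequence position -> fixed nucleotide written there."""
        pat = self.pattern
        return {
            self.start + off: ch
            for off, ch in zip(pat.fixed_offsets, pat.fixed_string)
        }

    @property
    def descriptor_name(self) -> str:
        """Canonical name of the descriptor this plant makes informative
        (feature type inferred from the pattern shape)."""
        from .encoder import FEATURE_TYPES

        pat = self.pattern
        for ft, mode, gaps in FEATURE_TYPES:
            if mode == pat.mode and gaps == pat.gap_lengths:
                end = self.start + pat.span - 1
                return f"{ft}:{pat.template}@{self.start}-{end}"
        raise ValueError(f"plant {self.template!r} matches no feature type")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset."""

    n_pos: int
    n_neg: int
    L: int = 41
    background: tuple[float, float, float, float] = DEFAULT_BACKGROUND
    plants: list[Plant] = field(default_factory=list)
    force_central_C: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or (bg < 0).any():
            raise ValueError(
                f"background must be 4 non-negative probabilities summing to 1, "
                f"got {self.background}"
            )
        central = (self.L + 1) // 2
        occupied: dict[int, str] = {}
        for plant in self.plants:
            if not (0.0 <= plant.p_pos <= 1.0 and 0.0 <= plant.p_neg <= 1.0):
                raise ValueError(f"plant {plant.template!r}: probabilities not in [0,1]")
            pat = plant.pattern
            if not 1 <= plant.start <= self.L - pat.span + 1:
                raise ValueError(
                    f"plant {plant.template!r} at start {plant.start} does not "
                    f"fit in a window of length {self.L}"
                )
            for pos, ch in plant.fixed_positions.items():
                if self.force_central_C and pos == central and ch != "C":
                    raise ValueError(
                        f"plant {plant.template!r} fixes the central position "
                        f"{central} to {ch!r}, conflicting with forced central C"
                    )
                if pos in occupied and occupied[pos] != ch:
                    raise ValueError(
                        f"plants conflict at position {pos}: "
                        f"{occupied[pos]!r} vs {ch!r}"
                    )
                occupied[pos] = ch


def generate(spec: SyntheticSpec) -> Dataset:
    """Draw a labeled dataset from a :class:`SyntheticSpec`.

    Residues are i.i.d. background; each plant then overwrites its fixed
    positions with class-conditional probability; finally the central
    residue is forced to C when flagged.  Byte-identical output for a
    fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    codes = np.arange(4)
    records: list[SequenceRecord] = []
    central_idx = (spec.L - 1) // 2
    for label, n, prefix in ((1, spec.n_pos, "pos"), (0, spec.n_neg, "neg")):
        mat = rng.choice(codes, size=(n, spec.L), p=spec.background)
        for plant in spec.plants:
            p = plant.p_pos if label == 1 else plant.p_neg
            hit = rng.random(n) < p
            for pos, ch in plant.fixed_positions.items():
                mat[hit, pos - 1] = ALPHABET.index(ch)
        if spec.force_central_C:
            mat[:, central_idx] = ALPHABET.index("C")
        width = len(str(max(n, 1)))
        for i in range(n):
            residues = "".join(ALPHABET[c] for c in mat[i])
            records.append(
                SequenceRecord(f"{prefix}_{i + 1:0{width}d}", residues, label)
            )
    return Dataset(records)


def benchmark_like(seed: int = 0) -> SyntheticSpec:
    """A spec mirroring the published benchmark's shape: 662 positive and
    662 negative 41-nt windows, uniform background, forced central C, and
    a moderate default plant set spanning three pattern modes.

    The plants give a learnable but imperfect signal, so end-to-end runs
    land in a realistic accuracy regime rather than at ceiling.
    """
    return SyntheticSpec(
        n_pos=662,
        n_neg=662,
        L=41,
        background=DEFAULT_BACKGROUND,
        plants=[
            Plant("GG-A", 11, 0.40, 0.08),
            Plant("CA-C", 24, 0.30, 0.08),
            Plant("AC---G", 28, 0.35, 0.08),
            Plant("U--AG", 34, 0.25, 0.08),
        ],
        force_central_C=True,
        seed=seed,
    )


def read_spec_config(path) -> SyntheticSpec:
    """Read a SyntheticSpec from a flat key=value config file.

    Recognized keys: n_pos, n_neg, L, seed, force_central_C,
    background (four comma-separated probabilities) and plants
    (semicolon-separated ``TEMPLATE@START:P_POS,P_NEG`` entries).
    """
    raw: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"config line {line!r} is not key=value")
            key, val = line.split("=", 1)
            raw[key.strip()] = val.strip()
    kwargs: dict = {}
    for key in ("n_pos", "n_neg", "L", "seed"):
        if key in raw:
            kwargs[key] = int(raw[key])
    if "force_central_C" in raw:
        kwargs["force_central_C"] = raw["force_central_C"].lower() in (
            "1", "true", "yes",
        )
    if "background" in raw:
        kwargs["background"] = tuple(
            float(x) for x in raw["background"].split(",")
        )
    if "plants" in raw and raw["plants"]:
        plants = []
        for entry in raw["plants"].split(";"):
            head, probs = entry.strip().split(":")
            template, start = head.split("@")
            p_pos, p_neg = (float(x) for x in probs.split(","))
            plants.append(Plant(template, int(start), p_pos, p_neg))
        kwargs["plants"] = plants
    if "n_pos" not in kwargs or "n_neg" not in kwargs:
        raise ValueError("config must set n_pos and n_neg")
    return SyntheticSpec(**kwargs)
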