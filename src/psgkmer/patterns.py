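"""Pattern families generating position-specific (gapped) k-mer descriptors.

A pattern is a short template of fixed nucleotides, optionally interleaved
with gap positions that match any nucleotide.  Six modes are supported:

====== ======================= ===== ============ ========
mode   shape                   gaps  span M       patterns
====== ======================= ===== ============ ========
PsM    N                       --    1            4
PsD    NN                      --    2            16
PsT    NNN                     --    3            64
PsMGD  N (g) NN                1-3   g+3          192
PsDGM  NN (g) N                1-3   g+3          192
PsMGMGM N (1) N (1) N          1,1   5            64
====== ======================= ===== ============ ========

Matching a pattern against a window of a sequence yields a binary
indicator: 1 iff every fixed nucleotide agrees with the residue at its
offset; gap positions are unconstrained.  Sliding the pattern over all
admissible start positions of a fixed-length window produces the
position-specific binary descriptors used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from itertools import product
from typing import Iterator

ALPHABET = "ACGU"
GAP_CHAR = "-"

# typographic dash variants occasionally seen in printed templates;
# en/em dashes stand for runs of two gap characters
_DASH_RUNS = {"–": "--", "—": "--", "−": "-"}


class Mode(str, Enum):
    """The six pattern-generation modes."""

    PSM = "PsM"
    PSD = "PsD"
    PST = "PsT"
    PSMGD = "PsMGD"
    PSDGM = "PsDGM"
    PSMGMGM = "PsMGMGM"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: fixed-nucleotide block sizes per mode, in template order
BLOCK_SIZES: dict[Mode, tuple[int, ...]] = {
    Mode.PSM: (1,),
    Mode.PSD: (2,),
    Mode.PST: (3,),
    Mode.PSMGD: (1, 2),
    Mode.PSDGM: (2, 1),
    Mode.PSMGMGM: (1, 1, 1),
}

#: admissible gap-length configurations per mode, ascending
GAP_CONFIGS: dict[Mode, tuple[tuple[int, ...], ...]] = {
    Mode.PSM: ((),),
    Mode.PSD: ((),),
    Mode.PST: ((),),
    Mode.PSMGD: ((1,), (2,), (3,)),
    Mode.PSDGM: ((1,), (2,), (3,)),
    Mode.PSMGMGM: ((1, 1),),
}


@dataclass(frozen=True)
class GappedPattern:
    """A fixed-nucleotide/gap template, e.g. blocks ("A", "CG") with one
    2-gap rendering as ``A--CG``.

    Parameters
    ----------
    mode:
        The generation mode the pattern belongs to.
    fixed_blocks:
        Ordered blocks of fixed nucleotides.
    gap_lengths:
        Gap sizes between consecutive blocks (empty for ungapped modes).
    """

    mode: Mode
    fixed_blocks: tuple[str, ...]
    gap_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        sizes = tuple(len(b) for b in self.fixed_blocks)
        if sizes != BLOCK_SIZES[self.mode]:
            raise ValueError(
                f"mode {self.mode} expects block sizes {BLOCK_SIZES[self.mode]}, "
                f"got {sizes}"
            )
        if self.gap_lengths not in GAP_CONFIGS[self.mode]:
            raise ValueError(
                f"mode {self.mode} does not admit gap lengths {self.gap_lengths}"
            )
        for block in self.fixed_blocks:
            for ch in block:
                if ch not in ALPHABET:
                    raise ValueError(f"fixed nucleotide {ch!r} not in {ALPHABET}")

    @property
    def template(self) -> str:
        """Rendered template: fixed blocks verbatim, one '-' per gap."""
        parts = [self.fixed_blocks[0]]
        for gap, block in zip(self.gap_lengths, self.fixed_blocks[1:]):
            parts.append(GAP_CHAR * gap)
            parts.append(block)
        return "".join(parts)

    @property
    def span(self) -> int:
        """Total pattern length M (fixed nucleotides + gaps)."""
        return sum(len(b) for b in self.fixed_blocks) + sum(self.gap_lengths)

    @property
    def n_fixed(self) -> int:
        return sum(len(b) for b in self.fixed_blocks)

    @property
    def fixed_string(self) -> str:
        """Fixed nucleotides concatenated in template order."""
        return "".join(self.fixed_blocks)

    @property
    def fixed_offsets(self) -> tuple[int, ...]:
        """0-based offsets of the fixed nucleotides within the template."""
        return tuple(
            i for i, ch in enumerate(self.template) if ch != GAP_CHAR
        )

    def __str__(self) -> str:
        return self.template


def render_template(pattern: GappedPattern) -> str:
    """Return the pattern's template string (``A--CG`` style)."""
    return pattern.template


def normalize_template(template: str) -> str:
    """Uppercase a template and replace typographic dash variants by '-'."""
    out = template.strip().upper()
    for dash, repl in _DASH_RUNS.items():
        out = out.replace(dash, repl)
    return out.replace("T", "U")


def parse_template(template: str, mode: Mode | None = None) -> GappedPattern:
    """Parse a template string such as ``A--CG`` back into a GappedPattern.

    The mode is inferred from the block/gap shape when not given.  Raises
    ``ValueError`` when the shape matches none of the supported modes or
    contradicts an explicitly requested one.
    """
    norm = normalize_template(template)
    if not norm:
        raise ValueError("empty template")
    blocks: list[str] = []
    gaps: list[int] = []
    cur = ""
    gap_run = 0
    for ch in norm:
        if ch == GAP_CHAR:
            if not cur and not blocks:
                raise ValueError(f"template {template!r} starts with a gap")
            if cur:
                blocks.append(cur)
                cur = ""
            gap_run += 1
        else:
            if ch not in ALPHABET:
                raise ValueError(f"invalid character {ch!r} in template {template!r}")
            if gap_run:
                gaps.append(gap_run)
                gap_run = 0
            cur += ch
    if gap_run:
        raise ValueError(f"template {template!r} ends with a gap")
    if cur:
        blocks.append(cur)

    sizes = tuple(len(b) for b in blocks)
    gap_tuple = tuple(gaps)
    candidates = [
        m
        for m in Mode
        if BLOCK_SIZES[m] == sizes and gap_tuple in GAP_CONFIGS[m]
    ]
    if mode is not None:
        if mode not in candidates:
            raise ValueError(
                f"template {template!r} is not a valid {mode} pattern"
            )
        chosen = mode
    elif len(candidates) == 1:
        chosen = candidates[0]
    elif not candidates:
        raise ValueError(
            f"template {template!r} matches no supported pattern mode"
        )
    else:  # pragma: no cover - shapes are mutually exclusive across modes
        raise ValueError(f"template {template!r} is ambiguous: {candidates}")
    return GappedPattern(chosen, tuple(blocks), gap_tuple)


def _blocks_from_string(fixed: str, sizes: tuple[int, ...]) -> tuple[str, ...]:
    blocks = []
    pos = 0
    for s in sizes:
        blocks.append(fixed[pos : pos + s])
        pos += s
    return tuple(blocks)


@lru_cache(maxsize=None)
def enumerate_mode_patterns(mode: Mode) -> tuple[GappedPattern, ...]:
    """All patterns of a mode in canonical order.

    Canonical order is: gap configuration ascending, then the concatenated
    fixed-nucleotide string lexicographic under A < C < G < U.  Counts per
    mode: PsM 4, PsD 16, PsT 64, PsMGD 192, PsDGM 192, PsMGMGM 64.
    """
    mode = Mode(mode)
    n_fixed = sum(BLOCK_SIZES[mode])
    out = []
    for gaps in GAP_CONFIGS[mode]:
        for combo in product(ALPHABET, repeat=n_fixed):
            blocks = _blocks_from_string("".join(combo), BLOCK_SIZES[mode])
            out.append(GappedPattern(mode, blocks, gaps))
    return tuple(out)


def match(pattern: GappedPattern, residues: str, start: int) -> int:
    """Binary indicator: does ``pattern`` match the window of ``residues``
    beginning at 1-based position ``start``?

    Gap positions match any nucleotide; every fixed nucleotide must agree
    with the residue at its offset.
    """
    m = pattern.span
    if not 1 <= start <= len(residues) - m + 1:
        raise ValueError(
            f"start {start} out of range for pattern span {m} on "
            f"sequence of length {len(residues)} (valid: 1..{len(residues) - m + 1})"
        )
    base = start - 1
    fixed = pattern.fixed_string
    for off, ch in zip(pattern.fixed_offsets, fixed):
        if residues[base + off] != ch:
            return 0
    return 1


def iter_windows(residues: str, span: int) -> Iterator[tuple[int, str]]:
    """Yield (1-based start, window) for every window of length ``span``."""
    for i in range(len(residues) - span + 1):
        yield i + 1, residues[i : i + span]
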