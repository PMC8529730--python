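"""The five classification features computed from a pairwise alignment
and an expression table.

* SS   -- sequence similarity: matched columns / alignment length.
* ICCB -- inverse count of consecutive identical-or-non-identical blocks,
          1/B where B is the number of maximal runs of identical
          (match) vs non-identical (mismatch or gap) columns.
* MMF  -- match-mismatch fraction: sum over blocks of (length - 1)
          divided by the alignment length, i.e. (L - B)/L.  High when
          matches and mismatches are clumped, low when they alternate.
* TZ   -- twilight-zone filter: pairs with SS below 20% cannot be called
          reliably and are excluded downstream (boundary kept: SS == 0.20
          passes).
* ELD  -- expression level difference: log2(|FPKM1 - FPKM2| + 1).

The block convention merges gap columns with adjacent mismatch columns
into single non-identical blocks, so the B blocks partition all L
columns; SS + MMF + ICCB are then mutually consistent (SS = matches/L,
ICCB = 1/B, MMF = 1 - B/L).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from picme.errors import InputError
from picme.pairalign import MATCH, AlignedPair
from picme.seqio import ExpressionTable

IDENTICAL, NON_IDENTICAL = "identical", "non-identical"

TZ_CUTOFF_DEFAULT = 0.20


@dataclass(frozen=True)
class BlockDecomposition:
    """Ordered maximal runs of identical vs non-identical columns."""

    runs: tuple[tuple[str, int], ...]
    length: int

    def __post_init__(self) -> None:
        if not self.runs:
            raise InputError("block decomposition needs at least one run")
        if sum(n for _, n in self.runs) != self.length:
            raise InputError("run lengths must sum to the alignment length")
        for (s1, _), (s2, _) in zip(self.runs, self.runs[1:]):
            if s1 == s2:
                raise InputError("adjacent runs must alternate in state")

    @property
    def n_blocks(self) -> int:
        return len(self.runs)


@dataclass(frozen=True)
class FeatureVector:
    ss: float
    iccb: float
    mmf: float
    eld: float
    tz_pass: bool

    def as_dict(self) -> dict:
        return {
            "ss": self.ss,
            "iccb": self.iccb,
            "mmf": self.mmf,
            "eld": self.eld,
            "tz_pass": self.tz_pass,
        }


MODEL_FEATURES = ["ss", "iccb", "mmf", "eld"]


def decompose_blocks(pair: AlignedPair) -> BlockDecomposition:
    """Run-length encode columns as identical (match) vs non-identical
    (mismatch or gap)."""
    runs: list[tuple[str, int]] = []
    for state in pair.states:
        kind = IDENTICAL if state == MATCH else NON_IDENTICAL
        if runs and runs[-1][0] == kind:
            runs[-1] = (kind, runs[-1][1] + 1)
        else:
            runs.append((kind, 1))
    return BlockDecomposition(tuple(runs), len(pair))


def sequence_similarity(pair: AlignedPair) -> float:
    """Fraction of matched columns over the full alignment length."""
    return sum(s == MATCH for s in pair.states) / len(pair)


def iccb(blocks: BlockDecomposition) -> float:
    """Reciprocal of the number of blocks."""
    return 1.0 / blocks.n_blocks


def mmf(blocks: BlockDecomposition) -> float:
    """Sum of (block length - 1) over all blocks, divided by alignment length."""
    return sum(n - 1 for _, n in blocks.runs) / blocks.length


def passes_twilight(ss: float, cutoff: float = TZ_CUTOFF_DEFAULT) -> bool:
    """True iff the pair clears the twilight-zone similarity cutoff.

    Pairs strictly below the cutoff are too diverged for a reliable
    paralog/isoform call and are excluded from training and prediction.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise InputError(f"twilight cutoff must be in [0, 1], got {cutoff}")
    return ss >= cutoff


def eld(fpkm1: float, fpkm2: float) -> float:
    """log2(|FPKM1 - FPKM2| + 1); symmetric, zero iff expression is equal."""
    if fpkm1 < 0 or fpkm2 < 0:
        raise InputError("FPKM values must be non-negative")
    return math.log2(abs(fpkm1 - fpkm2) + 1.0)


def extract_features(
    pair: AlignedPair,
    expr: ExpressionTable,
    tz_cutoff: float = TZ_CUTOFF_DEFAULT,
) -> FeatureVector:
    """Compute all five features for one aligned pair.

    The twilight filter is recorded, not applied: the vector is returned
    even for sub-threshold pairs so callers can report them as
    unclassifiable.
    """
    blocks = decompose_blocks(pair)
    ss = sequence_similarity(pair)
    return FeatureVector(
        ss=ss,
        iccb=iccb(blocks),
        mmf=mmf(blocks),
        eld=eld(expr[pair.id1], expr[pair.id2]),
        tz_pass=passes_twilight(ss, tz_cutoff),
    )
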