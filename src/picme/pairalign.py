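"""Pairwise global protein alignment.

The feature definitions downstream consume any pairwise alignment; the
default path is an affine-gap global (Needleman-Wunsch/Gotoh) aligner with
BLOSUM62 and BLAST-conventional penalties, implemented via
``Bio.Align.PairwiseAligner``.  An external-command hook lets users route
pairs through their own aligner (e.g. MAFFT fftnsi) for bit-compatible
reproduction of an existing pipeline.

Terminal gaps are penalized: fragmented and truncated transcripts are the
hard case this classifier exists for, and free end gaps would hide them.
"""

from __future__ import annotations

import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

from Bio import Align
from Bio.Align import substitution_matrices

from picme.errors import InputError, PicmeError
from picme.seqio import GAP, SequenceRecord, write_fasta

MATCH, MISMATCH, GAPSTATE = "match", "mismatch", "gap"


@dataclass(frozen=True)
class ScoringScheme:
    """Affine gap scoring: a gap of length k costs ``gap_open + k * gap_extend``."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise InputError("gap penalties must be positive")
        letters = set(self.matrix().alphabet)
        required = set("ACDEFGHIKLMNPQRSTVWYX")
        if not required <= letters:
            raise InputError(
                f"matrix {self.matrix_name!r} does not cover the amino-acid alphabet + X"
            )

    def matrix(self):
        return _load_matrix(self.matrix_name)


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    try:
        return substitution_matrices.load(name)
    except FileNotFoundError:
        raise InputError(f"unknown substitution matrix {name!r}") from None


@dataclass(frozen=True)
class AlignedPair:
    """Two equal-length gapped rows with per-column states.

    A column is ``match`` iff both residues are non-gap, equal, and neither
    is the ambiguity code X (ambiguity must not inflate similarity);
    ``gap`` iff exactly one row holds '-'; otherwise ``mismatch``.
    """

    id1: str
    id2: str
    row1: str
    row2: str
    states: tuple[str, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if not (len(self.row1) == len(self.row2) == len(self.states) >= 1):
            raise InputError("aligned rows/states must have equal positive length")

    @classmethod
    def from_rows(cls, id1: str, id2: str, row1: str, row2: str) -> "AlignedPair":
        if len(row1) != len(row2) or len(row1) == 0:
            raise InputError("aligned rows must have equal positive length")
        states = []
        for i, (a, b) in enumerate(zip(row1, row2)):
            if a == GAP and b == GAP:
                raise InputError(f"column {i}: gap in both rows")
            if a == GAP or b == GAP:
                states.append(GAPSTATE)
            elif a == b and a != "X":
                states.append(MATCH)
            else:
                states.append(MISMATCH)
        return cls(id1, id2, row1, row2, tuple(states))

    def __len__(self) -> int:
        return len(self.states)

    def ungapped(self) -> tuple[str, str]:
        return self.row1.replace(GAP, ""), self.row2.replace(GAP, "")

    def swapped(self) -> "AlignedPair":
        return AlignedPair.from_rows(self.id2, self.id1, self.row2, self.row1)


def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = scheme.matrix()
    # first gapped position costs open+extend so a length-k gap totals open + k*extend
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def alignment_score(a: str, b: str, scheme: ScoringScheme | None = None) -> float:
    """Optimal global alignment score for two residue strings."""
    scheme = scheme or ScoringScheme()
    return float(_make_aligner(scheme).score(a, b))


def align_pair(
    a: SequenceRecord, b: SequenceRecord, scheme: ScoringScheme | None = None
) -> AlignedPair:
    """Globally align two protein records under an affine-gap scheme.

    Deterministic: among co-optimal alignments the aligner's canonical
    first traceback is returned.
    """
    scheme = scheme or ScoringScheme()
    for rec in (a, b):
        if not rec.residues:
            raise InputError(f"sequence {rec.id!r} is empty")
        if set(rec.residues) == {"X"}:
            raise InputError(f"sequence {rec.id!r} consists only of ambiguity codes")
    aligner = _make_aligner(scheme)
    alignment = next(iter(aligner.align(a.residues, b.residues)))
    return AlignedPair.from_rows(a.id, b.id, str(alignment[0]), str(alignment[1]))


def external_aligner_hook(
    a: SequenceRecord, b: SequenceRecord, command_template: str
) -> AlignedPair:
    """Align a pair with a user-supplied command, e.g. ``mafft-fftnsi {input}``.

    The template must contain ``{input}``; the command must write a gapped
    two-record FASTA to stdout.  Any failure is surfaced with the captured
    diagnostics -- there is never a silent fallback to the builtin aligner.
    """
    from picme.seqio import read_aligned_pair

    if "{input}" not in command_template:
        raise InputError("aligner command template must contain '{input}'")
    with tempfile.TemporaryDirectory(prefix="picme-aln-") as tmp:
        fasta = Path(tmp) / "pair.fasta"
        write_fasta([a, b], fasta)
        cmd = [
            part.format(input=str(fasta))
            for part in shlex.split(command_template)
        ]
        try:
            proc = subprocess.run(cmd, capture_output=True, text=True)
        except FileNotFoundError:
            raise PicmeError(f"external aligner not found: {cmd[0]!r}") from None
        if proc.returncode != 0:
            raise PicmeError(
                f"external aligner exited with status {proc.returncode}:\n{proc.stderr}"
            )
        out = Path(tmp) / "pair.aln.fasta"
        out.write_text(proc.stdout)
        return read_aligned_pair(out)
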