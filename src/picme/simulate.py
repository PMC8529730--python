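"""Synthetic paralog/isoform pair generator.

Stands in for RNA-seq-derived transcriptome data with known truth labels:

* isoform pairs share one gene sequence and differ by 1-2 contiguous
  structural events (a skipped exon, or a mutually exclusive exon swap),
  plus a low rate of scattered single-residue errors mimicking assembly
  noise; their FPKMs are a gene-level total split between the two
  isoforms, hence correlated.
* paralog pairs are point-diverged duplicates (uniform substitutions over
  the 19 alternative residues, occasional indels with geometric lengths)
  whose FPKMs are drawn independently.

A fraction of all pairs has one member truncated at an end, mimicking
fragmented and misassembled transcripts -- the hard case that degrades
alignment-only features.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from picme.errors import InputError
from picme.seqio import (
    AMINO_ACIDS,
    ExpressionTable,
    PairList,
    PairRow,
    SequenceRecord,
    write_expression,
    write_fasta,
    write_pairs,
)

AA = np.array(list(AMINO_ACIDS))


@dataclass(frozen=True)
class SimParams:
    """Generator settings; defaults define the standard benchmark conditions."""

    n_pairs: int = 2000
    paralog_fraction: float = 0.5
    length_range: tuple[int, int] = (120, 600)
    # paralog divergence
    sub_rate_range: tuple[float, float] = (0.05, 0.60)
    indel_prob: float = 0.05  # per-site probability an indel event starts
    indel_mean_len: float = 3.0  # geometric mean length
    # isoform structure
    n_events_range: tuple[int, int] = (1, 2)
    event_types: tuple[str, ...] = ("skip", "swap")
    exon_len_range: tuple[int, int] = (15, 60)
    error_rate: float = 0.005  # scattered per-site assembly error
    # assembly fragmentation
    truncation_prob: float = 0.15
    truncation_frac_range: tuple[float, float] = (0.10, 0.40)
    # expression: log2 FPKM ~ Normal(mu, sigma) at the gene level
    expr_log2_mu: float = 2.0
    expr_log2_sigma: float = 1.5
    dirichlet_alpha: float = 2.0  # isoform split: Beta(alpha, alpha)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.paralog_fraction, self.indel_prob, self.error_rate, self.truncation_prob):
            if not 0.0 <= p <= 1.0:
                raise InputError(f"probability {p} outside [0, 1]")
        for lo, hi in (
            self.length_range,
            self.sub_rate_range,
            self.n_events_range,
            self.exon_len_range,
            self.truncation_frac_range,
        ):
            if lo > hi:
                raise InputError(f"degenerate range ({lo}, {hi})")
        if self.n_pairs < 1:
            raise InputError("n_pairs must be >= 1")
        if not self.event_types or set(self.event_types) - {"skip", "swap"}:
            raise InputError(f"unknown event types {self.event_types}")
        if self.sub_rate_range[0] < 0 or self.indel_mean_len < 1:
            raise InputError("rates must be non-negative, indel mean length >= 1")


@dataclass(frozen=True)
class SimPair:
    rec1: SequenceRecord
    rec2: SequenceRecord
    fpkm1: float
    fpkm2: float
    label: str


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(AA, size=length))


def _scatter_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        alternatives = [a for a in AMINO_ACIDS if a != chars[i]]
        chars[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def _truncate(seq: str, params: SimParams, rng: np.random.Generator) -> str:
    lo, hi = params.truncation_frac_range
    frac = rng.uniform(lo, hi)
    cut = max(1, int(round(frac * len(seq))))
    if cut >= len(seq):
        cut = len(seq) - 1
    return seq[cut:] if rng.random() < 0.5 else seq[:-cut]


def _maybe_truncate_pair(
    s1: str, s2: str, params: SimParams, rng: np.random.Generator
) -> tuple[str, str]:
    if rng.random() < params.truncation_prob:
        if rng.random() < 0.5:
            s1 = _truncate(s1, params, rng)
        else:
            s2 = _truncate(s2, params, rng)
    return s1, s2


def _gene_fpkm(params: SimParams, rng: np.random.Generator) -> float:
    return float(2.0 ** rng.normal(params.expr_log2_mu, params.expr_log2_sigma))


def generate_isoform_pair(
    params: SimParams, rng: np.random.Generator, pair_id: int = 0
) -> SimPair:
    """Two isoforms of one gene: identical outside 1-2 structural events."""
    length = int(rng.integers(params.length_range[0], params.length_range[1] + 1))
    base = _random_protein(length, rng)
    variant = base
    n_events = int(rng.integers(params.n_events_range[0], params.n_events_range[1] + 1))
    for _ in range(n_events):
        elen = int(rng.integers(params.exon_len_range[0], params.exon_len_range[1] + 1))
        elen = min(elen, max(1, len(variant) - 2))
        start = int(rng.integers(0, max(1, len(variant) - elen + 1)))
        event = params.event_types[int(rng.integers(len(params.event_types)))]
        if event == "skip":  # exon skip: the variant lacks one internal exon
            variant = variant[:start] + variant[start + elen :]
        else:  # mutually exclusive exon: same slot, different sequence
            variant = (
                variant[:start] + _random_protein(elen, rng) + variant[start + elen :]
            )
        if len(variant) == 0:
            variant = _random_protein(1, rng)
    s1 = _scatter_errors(base, params.error_rate, rng)
    s2 = _scatter_errors(variant, params.error_rate, rng)
    s1, s2 = _maybe_truncate_pair(s1, s2, params, rng)
    total = _gene_fpkm(params, rng)
    w = float(rng.beta(params.dirichlet_alpha, params.dirichlet_alpha))
    return SimPair(
        SequenceRecord(f"iso{pair_id}a", s1),
        SequenceRecord(f"iso{pair_id}b", s2),
        total * w,
        total * (1.0 - w),
        "isoform",
    )


def generate_paralog_pair(
    params: SimParams, rng: np.random.Generator, pair_id: int = 0
) -> SimPair:
    """Point-diverged duplicates with indels and independent expression."""
    length = int(rng.integers(params.length_range[0], params.length_range[1] + 1))
    ancestor = _random_protein(length, rng)
    rate = rng.uniform(*params.sub_rate_range)
    copy = _scatter_errors(ancestor, rate, rng)
    # indels: each site may start a deletion or insertion, geometric length
    if params.indel_prob > 0:
        out = []
        i = 0
        while i < len(copy):
            if rng.random() < params.indel_prob:
                k = int(rng.geometric(1.0 / params.indel_mean_len))
                if rng.random() < 0.5:
                    i += k  # deletion: skip k residues
                else:
                    out.append(_random_protein(k, rng))  # insertion
                    out.append(copy[i])
                    i += 1
            else:
                out.append(copy[i])
                i += 1
        copy = "".join(out) or _random_protein(1, rng)
    s1, s2 = _maybe_truncate_pair(ancestor, copy, params, rng)
    return SimPair(
        SequenceRecord(f"par{pair_id}a", s1),
        SequenceRecord(f"par{pair_id}b", s2),
        _gene_fpkm(params, rng),
        _gene_fpkm(params, rng),
        "paralog",
    )


def generate_pairs(params: SimParams) -> list[SimPair]:
    """All pairs for one benchmark draw, seed-reproducible."""
    rng = np.random.default_rng(params.seed)
    n_paralog = int(round(params.n_pairs * params.paralog_fraction))
    pairs: list[SimPair] = []
    for i in range(params.n_pairs):
        if i < n_paralog:
            pairs.append(generate_paralog_pair(params, rng, pair_id=i))
        else:
            pairs.append(generate_isoform_pair(params, rng, pair_id=i))
    return pairs


def generate_dataset(
    params: SimParams, out_prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Write <prefix>.fasta, <prefix>.expr.tsv, <prefix>.pairs.tsv.

    Class counts follow the paralog fraction (rounded); outputs are
    byte-identical for a fixed seed.
    """
    out_prefix = Path(out_prefix)
    pairs = generate_pairs(params)
    records, expr, rows = [], {}, []
    for p in pairs:
        records.extend([p.rec1, p.rec2])
        expr[p.rec1.id] = p.fpkm1
        expr[p.rec2.id] = p.fpkm2
        rows.append(PairRow(p.rec1.id, p.rec2.id, p.label))
    fasta = out_prefix.with_suffix(".fasta")
    expr_path = Path(str(out_prefix) + ".expr.tsv")
    pairs_path = Path(str(out_prefix) + ".pairs.tsv")
    comment = f"picme simulate seed={params.seed} n_pairs={params.n_pairs}"
    write_fasta(records, fasta)
    write_expression(ExpressionTable(expr), expr_path, header_comment=comment)
    write_pairs(PairList(rows), pairs_path, header_comment=comment)
    return fasta, expr_path, pairs_path
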