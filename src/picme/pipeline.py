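"""High-level plumbing: from sequences + expression + pair list to a
feature table ready for training or prediction."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from picme.errors import InputError
from picme.features import TZ_CUTOFF_DEFAULT, extract_features
from picme.pairalign import ScoringScheme, align_pair
from picme.seqio import (
    ExpressionTable,
    PairList,
    PairRow,
    SequenceRecord,
    read_aligned_pair,
)
from picme.simulate import SimParams, generate_pairs


def compute_feature_table(
    sequences: list[SequenceRecord],
    expression: ExpressionTable,
    pairs: PairList,
    scheme: ScoringScheme | None = None,
    tz_cutoff: float = TZ_CUTOFF_DEFAULT,
    aligned_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Align every pair (or load pre-aligned FASTA from ``aligned_dir``,
    expected as <id1>__<id2>.fasta) and compute its feature vector.

    Returns a frame with columns id1, id2, ss, iccb, mmf, eld, tz_pass, label.
    """
    by_id = {rec.id: rec for rec in sequences}
    rows = []
    for pair in pairs:
        aligned = None
        if aligned_dir is not None:
            candidate = Path(aligned_dir) / f"{pair.id1}__{pair.id2}.fasta"
            if candidate.exists():
                aligned = read_aligned_pair(candidate)
        if aligned is None:
            for tid in (pair.id1, pair.id2):
                if tid not in by_id:
                    raise InputError(f"pair references unknown sequence {tid!r}")
            aligned = align_pair(by_id[pair.id1], by_id[pair.id2], scheme)
        fv = extract_features(aligned, expression, tz_cutoff)
        rows.append({"id1": pair.id1, "id2": pair.id2, **fv.as_dict(), "label": pair.label})
    return pd.DataFrame(rows)


def simulated_feature_table(params: SimParams) -> pd.DataFrame:
    """Generate a synthetic benchmark in memory and featurize it."""
    sim_pairs = generate_pairs(params)
    sequences = [rec for p in sim_pairs for rec in (p.rec1, p.rec2)]
    expr = ExpressionTable(
        {p.rec1.id: p.fpkm1 for p in sim_pairs}
        | {p.rec2.id: p.fpkm2 for p in sim_pairs}
    )
    pair_list = PairList(
        [PairRow(p.rec1.id, p.rec2.id, p.label) for p in sim_pairs]
    )
    return compute_feature_table(sequences, expr, pair_list)
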