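"""Shared builders used across the test suite."""

import numpy as np
import pandas as pd

from picme.pairalign import AlignedPair


def pair_from_rows(row1: str, row2: str, id1: str = "s1", id2: str = "s2") -> AlignedPair:
    return AlignedPair.from_rows(id1, id2, row1, row2)


def random_aligned_pair(rng: np.random.Generator, length: int | None = None) -> AlignedPair:
    """Random alignment with arbitrary match/mismatch/gap columns (no gap-gap)."""
    from picme.seqio import AMINO_ACIDS

    L = length or int(rng.integers(1, 60))
    aa = list(AMINO_ACIDS)
    r1, r2 = [], []
    for _ in range(L):
        kind = rng.integers(4)
        if kind == 0:  # match
            c = aa[rng.integers(20)]
            r1.append(c)
            r2.append(c)
        elif kind == 1:  # mismatch
            i = rng.integers(20)
            j = (i + 1 + rng.integers(19)) % 20
            r1.append(aa[i])
            r2.append(aa[j])
        elif kind == 2:  # gap in row2
            r1.append(aa[rng.integers(20)])
            r2.append("-")
        else:  # gap in row1
            r1.append("-")
            r2.append(aa[rng.integers(20)])
    return pair_from_rows("".join(r1), "".join(r2))


def separable_feature_frame(n_per_class: int = 50, seed: int = 0) -> pd.DataFrame:
    """Linearly separable toy features: paralogs low ss, isoforms high ss."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_per_class):
        rows.append(
            dict(id1=f"p{i}a", id2=f"p{i}b", ss=rng.uniform(0.2, 0.4),
                 iccb=rng.uniform(0.01, 0.1), mmf=rng.uniform(0.3, 0.6),
                 eld=rng.uniform(2, 6), tz_pass=True, label="paralog")
        )
        rows.append(
            dict(id1=f"i{i}a", id2=f"i{i}b", ss=rng.uniform(0.8, 1.0),
                 iccb=rng.uniform(0.2, 1.0), mmf=rng.uniform(0.8, 1.0),
                 eld=rng.uniform(0, 1), tz_pass=True, label="isoform")
        )
    return pd.DataFrame(rows)


def null_feature_frame(n_rows: int = 200, seed: int = 0) -> pd.DataFrame:
    """Identically distributed classes: no signal at all."""
    rng = np.random.default_rng(seed)
    half = n_rows // 2
    return pd.DataFrame(
        dict(
            id1=[f"a{i}" for i in range(n_rows)],
            id2=[f"b{i}" for i in range(n_rows)],
            ss=rng.random(n_rows),
            iccb=rng.random(n_rows),
            mmf=rng.random(n_rows),
            eld=rng.random(n_rows) * 5,
            tz_pass=True,
            label=["paralog"] * half + ["isoform"] * (n_rows - half),
        )
    )
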