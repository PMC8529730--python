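"""Readers and writers for every on-disk format the tool touches.

Formats are deliberately plain: FASTA (unaligned, and gapped two-record
pairs), and tab-separated tables with a header line for expression values,
pair lists and feature tables.  Lines starting with ``#`` in TSV files are
treated as comments, which lets the CLI stamp provenance headers into its
outputs without breaking round-trips.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO

from picme.errors import InputError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")
GAP = "-"
LABELS = ("paralog", "isoform", "unknown")


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence: a predicted CDS translation of an assembled transcript."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise InputError("sequence record with empty id")
        if not self.residues:
            raise InputError(f"sequence {self.id!r} has empty residues")
        bad = set(self.residues) - VALID_RESIDUES
        if bad:
            raise InputError(
                f"sequence {self.id!r} contains invalid residues: {sorted(bad)}"
            )


def _clean_residues(seq_id: str, raw: str, *, allow_gaps: bool = False) -> str:
    """Upper-case, normalize '.' gaps to '-', replace non-standard letters by X."""
    out = []
    replaced = set()
    for ch in raw.upper():
        if ch == ".":
            ch = GAP
        if ch == GAP:
            if not allow_gaps:
                raise InputError(
                    f"sequence {seq_id!r} contains gap characters in ungapped FASTA"
                )
            out.append(ch)
        elif ch in VALID_RESIDUES:
            out.append(ch)
        else:
            replaced.add(ch)
            out.append("X")
    if replaced:
        warnings.warn(
            f"sequence {seq_id!r}: non-amino-acid characters {sorted(replaced)} "
            "replaced by X",
            stacklevel=3,
        )
    return "".join(out)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a protein FASTA file into records, preserving order.

    Residues are upper-cased; characters outside the 20-letter alphabet
    (other than X) are replaced by X with a warning.  Duplicate IDs and
    empty files are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise InputError(f"duplicate sequence ID {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = _clean_residues(rec.id, str(rec.seq))
        records.append(SequenceRecord(rec.id, residues, rec.description))
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


def read_aligned_pair(path: str | Path):
    """Read a gapped two-record FASTA (e.g. MAFFT output) into an AlignedPair.

    Both rows must have equal length; '.' gaps are normalized to '-'; a
    column gapped in both rows is rejected.
    """
    from picme.pairalign import AlignedPair  # local import: avoids cycle

    raw = list(SeqIO.parse(str(path), "fasta"))
    if len(raw) != 2:
        raise InputError(f"{path}: expected exactly 2 aligned records, got {len(raw)}")
    rows = [_clean_residues(r.id, str(r.seq), allow_gaps=True) for r in raw]
    if len(rows[0]) != len(rows[1]):
        raise InputError(
            f"{path}: aligned rows differ in length ({len(rows[0])} vs {len(rows[1])})"
        )
    return AlignedPair.from_rows(raw[0].id, raw[1].id, rows[0], rows[1])


class ExpressionTable(Mapping[str, float]):
    """Transcript ID -> FPKM.  Missing IDs raise, never silently return 0."""

    def __init__(self, values: Mapping[str, float]):
        bad = {k: v for k, v in values.items() if v < 0}
        if bad:
            raise InputError(f"negative FPKM values: {bad}")
        self._values = dict(values)

    def __getitem__(self, transcript_id: str) -> float:
        try:
            return self._values[transcript_id]
        except KeyError:
            raise InputError(
                f"no expression value for transcript {transcript_id!r}"
            ) from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._values)

    def __len__(self) -> int:
        return len(self._values)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ExpressionTable):
            return self._values == other._values
        return NotImplemented


@dataclass(frozen=True)
class PairRow:
    id1: str
    id2: str
    label: str = "unknown"

    def __post_init__(self) -> None:
        if self.id1 == self.id2:
            raise InputError(f"self-pair ({self.id1!r}, {self.id1!r}) is not allowed")
        if self.label not in LABELS:
            raise InputError(
                f"pair ({self.id1}, {self.id2}): label {self.label!r} "
                f"not one of {LABELS}"
            )

    @property
    def key(self) -> tuple[str, str]:
        """Unordered pair key; pair direction carries no information."""
        return tuple(sorted((self.id1, self.id2)))  # type: ignore[return-value]


@dataclass
class PairList:
    rows: list[PairRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for row in self.rows:
            if row.key in seen:
                raise InputError(f"duplicate pair {row.key}")
            seen.add(row.key)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[PairRow]:
        return iter(self.rows)


def _read_tsv(path: str | Path, expected_cols: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty file") from None
    missing = [c for c in expected_cols if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing} (found {list(df.columns)})")
    return df


def read_expression(path: str | Path) -> ExpressionTable:
    """Read a two-column TSV 'transcript_id<TAB>fpkm' with a header line."""
    df = _read_tsv(path, ["transcript_id", "fpkm"])
    values: dict[str, float] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        tid = row.transcript_id
        try:
            fpkm = float(row.fpkm)
        except (TypeError, ValueError):
            raise InputError(
                f"{path} line {i}: malformed FPKM value {row.fpkm!r}"
            ) from None
        if fpkm < 0:
            raise InputError(f"{path} line {i}: negative FPKM for {tid!r}")
        if tid in values:
            raise InputError(f"{path} line {i}: duplicate transcript {tid!r}")
        values[tid] = fpkm
    if not values:
        raise InputError(f"{path}: no expression rows")
    return ExpressionTable(values)


def write_expression(table: ExpressionTable, path: str | Path, *, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("transcript_id\tfpkm\n")
        for tid, fpkm in table.items():
            fh.write(f"{tid}\t{fpkm:.6g}\n")


def read_pairs(path: str | Path) -> PairList:
    """Read a pair-list TSV 'id1<TAB>id2<TAB>label' (label optional, default unknown)."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty file") from None
    if "id1" not in df.columns or "id2" not in df.columns:
        raise InputError(f"{path}: expected columns id1, id2[, label]")
    rows = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        label = getattr(row, "label", "unknown")
        if label is None or (isinstance(label, float)) or label == "":
            label = "unknown"
        try:
            rows.append(PairRow(row.id1, row.id2, label))
        except InputError as exc:
            raise InputError(f"{path} line {i}: {exc}") from None
    return PairList(rows)


def write_pairs(pairs: PairList, path: str | Path, *, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("id1\tid2\tlabel\n")
        for row in pairs:
            fh.write(f"{row.id1}\t{row.id2}\t{row.label}\n")


FEATURE_COLUMNS = ["id1", "id2", "ss", "iccb", "mmf", "eld", "tz_pass", "label"]


def write_features(dataset: pd.DataFrame, path: str | Path, *, header_comment: str | None = None) -> None:
    """Write a feature table TSV with columns id1,id2,ss,iccb,mmf,eld,tz_pass,label."""
    missing = [c for c in FEATURE_COLUMNS if c not in dataset.columns]
    if missing:
        raise InputError(f"feature table missing columns {missing}")
    out = dataset[FEATURE_COLUMNS].copy()
    out["tz_pass"] = out["tz_pass"].astype(bool)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_features(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, FEATURE_COLUMNS)
    for col in ("ss", "iccb", "mmf", "eld"):
        df[col] = df[col].astype(float)
    df["tz_pass"] = df["tz_pass"].map(
        {"True": True, "False": False, "true": True, "false": False}
    )
    if df["tz_pass"].isna().any():
        raise InputError(f"{path}: malformed tz_pass column")
    return df
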