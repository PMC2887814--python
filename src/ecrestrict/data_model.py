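"""Shared domain types and file readers/writers.

Every stage of the pipeline exchanges four kinds of objects:

* :class:`ExpressionMatrix` — genes x samples, non-negative normalized
  signal values (the units are whatever the upstream normalization
  produced; the statistics only use ratios of group means).
* :class:`SampleSheet` — per-sample annotation: cell type, lineage
  (``target`` vs ``background``), optional subgroup, replicate index.
* :class:`GeneSetCollection` — named gene sets (GMT format) used by the
  over-representation stage.
* :class:`SequenceRecord` — identifier + nucleotide sequence; RNA is
  normalized to the DNA alphabet (U -> T) on construction so that all
  seed-match comparisons happen in one canonical alphabet.

File dialects: expression matrices and sample sheets are UTF-8 TSV; the
first header cell of an expression matrix is literally ``gene_id``.
Missing values are not permitted — the downstream statistics assume
complete rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import DataFormatError, UsageError

TARGET = "target"
BACKGROUND = "background"

_SEQ_ALPHABET = set("ACGTN")


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise DataFormatError(f"duplicate {what} {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of non-negative normalized signals."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (n_genes, n_samples), float64

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        _check_unique(self.gene_ids, "gene_id")
        _check_unique(self.sample_ids, "sample_id")
        if values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataFormatError(
                f"value matrix shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(values)):
            raise DataFormatError("expression values must be finite (no NaN/inf)")
        if np.any(values < 0):
            raise DataFormatError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tuple(frame.index), tuple(frame.columns), frame.to_numpy(dtype=float))

    def column_values(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Sub-matrix (all genes) for the given samples, in the given order."""
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            idx = [pos[s] for s in sample_ids]
        except KeyError as exc:
            raise UsageError(f"unknown sample id {exc.args[0]!r}") from exc
        return self.values[:, idx]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            idx = [pos[g] for g in gene_ids]
        except KeyError as exc:
            raise UsageError(f"unknown gene id {exc.args[0]!r}") from exc
        return ExpressionMatrix(tuple(gene_ids), self.sample_ids, self.values[idx, :])


_SHEET_COLUMNS = ("sample_id", "cell_type", "lineage", "subgroup", "replicate")


@dataclass(frozen=True)
class SampleSheet:
    """Per-sample annotations: cell type, lineage, subgroup, replicate."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.frame.copy()
        missing = [c for c in _SHEET_COLUMNS if c not in frame.columns]
        if missing:
            raise DataFormatError(f"sample sheet missing columns {missing}")
        frame = frame[list(_SHEET_COLUMNS)]
        frame["sample_id"] = frame["sample_id"].astype(str)
        frame["subgroup"] = frame["subgroup"].fillna("").astype(str)
        _check_unique(list(frame["sample_id"]), "sample_id")
        bad = set(frame["lineage"]) - {TARGET, BACKGROUND}
        if bad:
            raise DataFormatError(f"lineage must be 'target' or 'background', got {bad}")
        if not (frame["lineage"] == TARGET).any():
            raise DataFormatError("sample sheet has no target samples")
        if not (frame["lineage"] == BACKGROUND).any():
            raise DataFormatError("sample sheet has no background samples")
        reps = frame["replicate"].astype(int)
        if (reps < 1).any():
            raise DataFormatError("replicate indices must be >= 1")
        frame["replicate"] = reps
        object.__setattr__(self, "frame", frame)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.frame["sample_id"])

    def samples_where(self, *, lineage: str | None = None,
                      subgroup: str | None = None,
                      cell_type: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.frame.index)
        if lineage is not None:
            mask &= self.frame["lineage"] == lineage
        if subgroup is not None:
            mask &= self.frame["subgroup"] == subgroup
        if cell_type is not None:
            mask &= self.frame["cell_type"] == cell_type
        return list(self.frame.loc[mask, "sample_id"])

    @property
    def target_samples(self) -> list[str]:
        return self.samples_where(lineage=TARGET)

    @property
    def background_samples(self) -> list[str]:
        return self.samples_where(lineage=BACKGROUND)

    @property
    def target_subgroups(self) -> list[str]:
        sub = self.frame.loc[self.frame["lineage"] == TARGET, "subgroup"]
        return sorted({s for s in sub if s})

    @property
    def target_cell_types(self) -> list[str]:
        ct = self.frame.loc[self.frame["lineage"] == TARGET, "cell_type"]
        return sorted(set(ct))

    def subgroup_of_cell_type(self, cell_type: str) -> str:
        rows = self.frame.loc[self.frame["cell_type"] == cell_type, "subgroup"]
        if rows.empty:
            raise UsageError(f"unknown cell type {cell_type!r}")
        return rows.iloc[0]

    def check_matches(self, matrix: ExpressionMatrix) -> None:
        """Every matrix sample must appear exactly once in the sheet."""
        sheet_ids = set(self.sample_ids)
        matrix_ids = set(matrix.sample_ids)
        if sheet_ids != matrix_ids:
            raise DataFormatError(
                "sample sheet / matrix mismatch: "
                f"only-in-sheet={sorted(sheet_ids - matrix_ids)[:5]}, "
                f"only-in-matrix={sorted(matrix_ids - sheet_ids)[:5]}"
            )


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise DataFormatError(f"gene set {self.set_id!r} has no members")
        _check_unique(self.members, f"member of set {self.set_id!r}")


@dataclass(frozen=True)
class GeneSetCollection:
    sets: Mapping[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, gs in self.sets.items():
            if key != gs.set_id:
                raise DataFormatError(f"set key {key!r} != set_id {gs.set_id!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.sets[set_id]


@dataclass(frozen=True)
class SequenceRecord:
    """Nucleotide sequence; stored uppercase in the DNA alphabet (U -> T)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = str(self.sequence).upper().replace("U", "T")
        if not seq:
            raise DataFormatError(f"sequence record {self.id!r} is empty")
        bad = set(seq) - _SEQ_ALPHABET
        if bad:
            raise DataFormatError(
                f"sequence record {self.id!r} contains invalid symbols {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)


# ---------------------------------------------------------------------------
# Readers / writers


def read_expression_tsv(path) -> ExpressionMatrix:
    """Read a genes x samples TSV whose first header cell is ``gene_id``."""
    with open(path, encoding="utf-8") as handle:
        header = handle.readline().rstrip("\n").split("\t")
    if not header or header[0] != "gene_id":
        raise DataFormatError(
            f"{path}: first header cell must be 'gene_id', got "
            f"{header[0]!r}" if header else f"{path}: empty file"
        )
    sample_ids = header[1:]
    # pandas silently renames duplicate columns, so check the raw header
    _check_unique(sample_ids, "sample_id")
    frame = pd.read_csv(path, sep="\t", header=0, dtype=str)
    gene_ids = list(frame.iloc[:, 0].astype(str))
    try:
        values = frame.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise DataFormatError(f"{path}: non-numeric expression value ({exc})") from exc
    if np.isnan(values).any():
        raise DataFormatError(f"{path}: missing expression values are not permitted")
    return ExpressionMatrix(tuple(gene_ids), tuple(sample_ids), values)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    frame = matrix.to_frame()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t", float_format="%.10g")


def read_sample_sheet(path) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", header=0, dtype={"sample_id": str})
    return SampleSheet(frame)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: ``set_id TAB description TAB member...`` per line."""
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            set_id, description = fields[0], fields[1]
            members: list[str] = []
            seen: set[str] = set()
            dup = False
            for m in fields[2:]:
                if not m:
                    continue
                if m in seen:
                    dup = True
                    continue
                seen.add(m)
                members.append(m)
            if dup:
                warnings.warn(f"{path}:{lineno}: duplicate members in set "
                              f"{set_id!r} were deduplicated")
            if set_id in sets:
                raise DataFormatError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            sets[set_id] = GeneSet(set_id, description, tuple(members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for gs in collection:
            handle.write("\t".join([gs.set_id, gs.description, *gs.members]) + "\n")


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA records in file order, normalizing U -> T."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.sequence}\n")
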