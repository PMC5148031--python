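"""Reading, validation and writing of the four input artifacts.

All tables are tab-separated UTF-8 text; lines starting with ``#`` are
ignored. Gene and sample identifiers are opaque strings. Validation is
total: every malformed input raises :class:`~rifseq.errors.ValidationError`
with the offending coordinates, never a silent coercion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from rifseq.errors import ValidationError

__all__ = [
    "CountMatrix",
    "SampleDesign",
    "read_counts",
    "write_counts",
    "read_gene_meta",
    "write_gene_meta",
    "read_trf_list",
    "write_trf_list",
    "read_design",
    "write_design",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass(frozen=True)
class CountMatrix:
    """Non-negative integer read counts per (gene, sample).

    ``counts`` is a genes x samples DataFrame with gene identifiers as the
    index and sample identifiers as columns, both unique, in file order.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise ValidationError(
                f"count matrix must be at least 2x2, got {df.shape[0]}x{df.shape[1]}"
            )
        _check_unique(list(df.index), "gene")
        _check_unique(list(df.columns), "sample")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            bad = df.columns[
                [not np.issubdtype(t, np.number) for t in df.dtypes]
            ][0]
            raise ValidationError(f"non-numeric counts in sample {bad!r}")
        if np.isnan(values.astype(float)).any():
            g, s = np.argwhere(np.isnan(values.astype(float)))[0]
            raise ValidationError(
                f"missing count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if (values < 0).any():
            g, s = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        if not np.array_equal(values, np.floor(values)):
            frac = values != np.floor(values)
            g, s = np.argwhere(frac)[0]
            raise ValidationError(
                f"non-integer count at gene {df.index[g]!r}, sample {df.columns[s]!r}"
            )
        canon = df.astype(np.int64)
        canon.index = pd.Index([str(g) for g in canon.index], name="gene_id")
        canon.columns = pd.Index([str(s) for s in canon.columns], name=None)
        object.__setattr__(self, "counts", canon)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def lib_sizes(self) -> pd.Series:
        """Per-sample library size (column sum of counts)."""
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class SampleDesign:
    """Sample-to-condition assignment plus the ordered contrast (A, B).

    Correlations within a condition need at least 3 samples, so both
    contrast conditions must have >= 3 samples.
    """

    table: pd.DataFrame  # columns: sample_id, condition
    contrast: tuple[str, str]

    def __post_init__(self) -> None:
        tab = self.table
        for col in ("sample_id", "condition"):
            if col not in tab.columns:
                raise ValidationError(f"design is missing required column {col!r}")
        _check_unique(list(tab["sample_id"]), "sample")
        a, b = self.contrast
        if a == b:
            raise ValidationError(f"contrast conditions must differ, got ({a!r}, {b!r})")
        for cond in (a, b):
            n = int((tab["condition"] == cond).sum())
            if n < 3:
                raise ValidationError(
                    f"condition {cond!r} has {n} samples; >= 3 required per contrast group"
                )
        # canonical order: samples of condition A, then B, then the rest,
        # each sorted by id, so permuted input rows yield an identical design
        order = pd.Categorical(
            tab["condition"].map(lambda c: 0 if c == a else (1 if c == b else 2))
        )
        canon = tab.assign(_k=order).sort_values(["_k", "sample_id"]).drop(columns="_k")
        object.__setattr__(self, "table", canon.reset_index(drop=True))

    @property
    def condition_a(self) -> str:
        return self.contrast[0]

    @property
    def condition_b(self) -> str:
        return self.contrast[1]

    @property
    def samples_a(self) -> list[str]:
        t = self.table
        return list(t.loc[t["condition"] == self.condition_a, "sample_id"])

    @property
    def samples_b(self) -> list[str]:
        t = self.table
        return list(t.loc[t["condition"] == self.condition_b, "sample_id"])

    def validate_against(self, counts: CountMatrix) -> None:
        """Check the design covers exactly the samples of ``counts``."""
        design_samples = set(self.table["sample_id"])
        matrix_samples = set(counts.sample_ids)
        missing = sorted(matrix_samples - design_samples)
        if missing:
            raise ValidationError(f"samples absent from design: {missing}")
        extra = sorted(design_samples - matrix_samples)
        if extra:
            raise ValidationError(f"design samples absent from count matrix: {extra}")


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", comment="#", dtype=str, **kwargs)
    except pd.errors.ParserError as exc:  # ragged rows carry the line number
        raise ValidationError(f"{path}: malformed TSV: {exc}") from exc


def read_counts(path: str | Path) -> CountMatrix:
    """Read a genes x samples TSV (first column gene ids, header sample ids)."""
    with open(path, encoding="utf-8") as fh:  # pandas mangles duplicate headers
        for line in fh:
            if line.strip() and not line.startswith("#"):
                _check_unique(line.rstrip("\n").split("\t")[1:], "sample")
                break
    raw = _read_tsv(path, index_col=0)
    raw.index = raw.index.astype(str)
    if raw.isna().any().any():
        g = raw.index[raw.isna().any(axis=1)][0]
        s = raw.columns[raw.isna().any(axis=0)][0]
        raise ValidationError(f"{path}: missing value near gene {g!r}, sample {s!r}")
    try:
        num = raw.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        for s in raw.columns:
            col = pd.to_numeric(raw[s], errors="coerce")
            if col.isna().any():
                g = raw.index[col.isna()][0]
                raise ValidationError(
                    f"{path}: non-numeric count at gene {g!r}, sample {s!r}"
                ) from exc
        raise
    try:
        return CountMatrix(num)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_meta(path: str | Path, counts: CountMatrix | None = None) -> pd.DataFrame:
    """Read gene metadata (columns ``gene_id``, ``length_bp``).

    Returns a DataFrame indexed by gene_id with an integer ``length_bp``
    column. If ``counts`` is given, every gene of the matrix must have
    exactly one metadata row.
    """
    tab = _read_tsv(path)
    for col in ("gene_id", "length_bp"):
        if col not in tab.columns:
            raise ValidationError(f"{path}: gene metadata is missing column {col!r}")
    _check_unique(list(tab["gene_id"]), "gene")
    lengths = pd.to_numeric(tab["length_bp"], errors="coerce")
    if lengths.isna().any() or (lengths < 1).any() or (lengths != np.floor(lengths)).any():
        g = tab["gene_id"][lengths.isna() | (lengths < 1) | (lengths != np.floor(lengths))].iloc[0]
        raise ValidationError(f"{path}: length_bp must be a positive integer (gene {g!r})")
    meta = pd.DataFrame({"length_bp": lengths.astype(np.int64).to_numpy()},
                        index=pd.Index(tab["gene_id"].astype(str), name="gene_id"))
    if counts is not None:
        missing = sorted(set(counts.gene_ids) - set(meta.index))
        if missing:
            raise ValidationError(
                f"{path}: genes in counts without metadata: {missing[:10]}"
                + ("..." if len(missing) > 10 else "")
            )
        meta = meta.loc[counts.gene_ids]
    return meta


def write_gene_meta(meta: pd.DataFrame, path: str | Path) -> None:
    meta[["length_bp"]].to_csv(path, sep="\t", index_label="gene_id")


def read_trf_list(path: str | Path) -> list[str]:
    """Read a regulator list, one identifier per line (``#`` comments allowed)."""
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    _check_unique(ids, "regulator")
    return ids


def write_trf_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for x in ids:
            fh.write(f"{x}\n")


def annotate_trfs(trf_ids: Sequence[str], counts: CountMatrix) -> pd.DataFrame:
    """Flag each regulator id as measured (present in the matrix) or not.

    Unmeasured regulators are retained, not dropped, so downstream consensus
    output can still report knowledge-base regulators without expression
    support.
    """
    measured = set(counts.gene_ids)
    return pd.DataFrame(
        {"measured": [x in measured for x in trf_ids]},
        index=pd.Index(list(trf_ids), name="trf_id"),
    )


def read_design(path: str | Path, contrast: tuple[str, str]) -> SampleDesign:
    """Read the sample design sheet (columns ``sample_id``, ``condition``)."""
    tab = _read_tsv(path)
    try:
        return SampleDesign(tab, tuple(contrast))  # type: ignore[arg-type]
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_design(design: SampleDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)
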