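"""Expression-matrix container, TSV I/O and quantile normalization.

The pipeline operates on a probe-set x sample grid of log2 intensities.
Cross-sample comparability is established by quantile normalization: every
sample's value distribution is forced onto the common distribution of
rank-wise means, the same cross-sample core used by RMA for microarrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

ScaleTag = Literal["linear", "log2"]

__all__ = [
    "ExpressionMatrix",
    "IdentifierError",
    "MatrixFormatError",
    "read_matrix",
    "write_matrix",
    "to_log2",
    "normalize_quantile",
]


class IdentifierError(ValueError):
    """Duplicate or unknown probe/sample identifiers."""


class MatrixFormatError(ValueError):
    """Malformed matrix file or degenerate matrix shape."""


def _check_unique(ids: Iterable[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    seen: set[str] = set()
    dups = [i for i in ids if i in seen or seen.add(i)]  # type: ignore[func-returns-value]
    if dups:
        raise IdentifierError(f"duplicate {what} identifier(s): {sorted(set(dups))[:5]}")
    return ids


@dataclass(frozen=True)
class ExpressionMatrix:
    """Probe-set x sample grid with ordered, unique identifiers.

    Parameters
    ----------
    probe_ids :
        Row identifiers (probe sets), order meaningful.
    sample_ids :
        Column identifiers (samples/arrays), order meaningful.
    values :
        Real-valued grid, shape ``(len(probe_ids), len(sample_ids))``.
    scale_tag :
        ``"linear"`` for raw intensities (all > 0) or ``"log2"``.
        The scale must be declared by the caller; silent auto-detection is
        refused because a mis-declared scale corrupts the pitch mapping.
    """

    probe_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    scale_tag: ScaleTag = "log2"

    def __post_init__(self) -> None:
        object.__setattr__(self, "probe_ids", tuple(_check_unique(self.probe_ids, "probe")))
        object.__setattr__(self, "sample_ids", tuple(_check_unique(self.sample_ids, "sample")))
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise MatrixFormatError(f"values must be 2-D, got {vals.ndim}-D")
        if vals.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise MatrixFormatError(
                f"shape {vals.shape} does not match {len(self.probe_ids)} probes "
                f"x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(vals)):
            raise MatrixFormatError("values contain non-finite entries")
        if self.scale_tag not in ("linear", "log2"):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.scale_tag == "linear" and vals.size and vals.min() <= 0:
            raise MatrixFormatError("linear-scale matrix contains non-positive values")
        object.__setattr__(self, "values", vals)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.probe_ids), columns=list(self.sample_ids))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, scale_tag: ScaleTag = "log2") -> "ExpressionMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy(float), scale_tag)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise IdentifierError(f"unknown sample id {sample_id!r}") from None

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_index(sample_id)]


def read_matrix(path: str | Path, scale_hint: ScaleTag) -> ExpressionMatrix:
    """Read a tab-separated matrix (header row = sample ids, first column = probe ids).

    ``scale_hint`` declares whether the stored values are linear intensities
    or log2 intensities; there is deliberately no auto-detection.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise MatrixFormatError(f"{path}: empty file")
        cols = header.split("\t")
        sample_ids = cols[1:]
        if not sample_ids:
            raise MatrixFormatError(f"{path}: header defines no sample columns")
        probe_ids: list[str] = []
        rows: list[list[float]] = []
        ncol = len(sample_ids)
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != ncol + 1:
                raise MatrixFormatError(
                    f"{path}:{lineno}: expected {ncol + 1} fields, found {len(parts)}"
                )
            probe_ids.append(parts[0])
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError:
                bad = next(v for v in parts[1:] if not _is_number(v))
                col = sample_ids[parts[1:].index(bad)]
                raise MatrixFormatError(
                    f"{path}:{lineno}: non-numeric value {bad!r} in row {parts[0]!r}, column {col!r}"
                ) from None
    if not probe_ids:
        raise MatrixFormatError(f"{path}: no data rows")
    return ExpressionMatrix(tuple(probe_ids), tuple(sample_ids), np.array(rows, float), scale_hint)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV, values at 17 significant digits (lossless for float64)."""
    if m.n_samples == 0 or m.n_probes == 0:
        raise MatrixFormatError("refusing to write an empty matrix")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("probe_id\t" + "\t".join(m.sample_ids) + "\n")
        for pid, row in zip(m.probe_ids, m.values):
            fh.write(pid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def to_log2(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert a linear-scale matrix to log2; no-op when already log2."""
    if m.scale_tag == "log2":
        return m
    if m.values.size and m.values.min() <= 0:
        raise MatrixFormatError("cannot log2-transform non-positive values")
    return replace(m, values=np.log2(m.values), scale_tag="log2")


def normalize_quantile(m: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns so all samples share one value distribution.

    Each column's values are replaced by the mean, across samples, of the
    values holding the same rank; ties within a column receive the mean of
    the rank-means over the tied positions (so the matrix total is preserved
    exactly). Within-column rank order is preserved and the operation is
    idempotent.
    """
    if m.scale_tag != "log2":
        raise MatrixFormatError("normalize_quantile expects a log2-scale matrix")
    if m.n_samples < 2:
        raise MatrixFormatError("quantile normalization needs at least 2 samples")
    vals = m.values
    rank_means = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    n = vals.shape[0]
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        # tie-group boundaries: start index of each run of equal values
        starts = np.flatnonzero(np.r_[True, np.diff(sorted_col) != 0])
        ends = np.r_[starts[1:], n]
        for a, b in zip(starts, ends):
            out[order[a:b], j] = rank_means[a:b].mean()
    return replace(m, values=out)
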