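"""Expression matrix container, normalization, and TSV I/O.

The normalization chain mirrors the cohort-processing convention for the
MMP signature: raw counts -> non-detected replacement (minimal detected
signal per gene) -> log2(count + 1) -> per-gene cohort-median
standardization.  The matrix carries its processing ``state`` so the chain
cannot be applied out of order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ExpressionStateError",
    "read_expression_table",
    "write_expression_table",
    "log_normalize",
    "replace_nondetected",
    "standardize_by_median",
]

_STATES = {"raw_counts", "log2", "standardized"}


class ExpressionStateError(ValueError):
    """Operation applied to a matrix in the wrong normalization state."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a detectability mask.

    Attributes
    ----------
    values : pandas.DataFrame
        Rows are genes, columns are samples.
    detect_mask : pandas.DataFrame of bool
        True where the measurement was detected.  Zeros in raw counts are
        non-detected by definition.
    state : str
        ``raw_counts``, ``log2`` or ``standardized``.
    """

    values: pd.DataFrame
    detect_mask: pd.DataFrame | None = None
    state: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.state not in _STATES:
            raise ValueError(f"state must be one of {_STATES}, got {self.state!r}")
        # rename_axis (not in-place .name=) so shared Index objects from
        # caller frames are never mutated
        self.values = self.values.astype(float).rename_axis(
            index="gene_id", columns=None
        )
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.detect_mask is None:
            if self.state == "raw_counts":
                self.detect_mask = self.values > 0
            else:
                self.detect_mask = pd.DataFrame(
                    True, index=self.values.index, columns=self.values.columns
                )
        if self.detect_mask.shape != self.values.shape:
            raise ValueError("detect_mask shape must match values")
        self.detect_mask = self.detect_mask.astype(bool)
        if self.state == "raw_counts" and (self.values.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.copy(), self.detect_mask.copy(), self.state
        )


def read_expression_table(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (gene-id first column, sample header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no sample columns found")

    def _numeric_like(c) -> bool:
        try:
            float(str(c))
            return True
        except ValueError:
            return False

    if any(_numeric_like(c) for c in df.columns):
        raise ValueError(
            f"{path}: numeric column names suggest a missing sample-id header row"
        )
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric expression entry") from exc
    if (values.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative expression entries are not allowed")
    return ExpressionMatrix(values)


def write_expression_table(m: ExpressionMatrix, path) -> None:
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        m.values.to_csv(fh, sep="\t", lineterminator="\n")


def log_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(count + 1) per cell; requires ``raw_counts`` state."""
    if m.state != "raw_counts":
        raise ExpressionStateError(
            f"log_normalize requires raw_counts, matrix is {m.state}"
        )
    return ExpressionMatrix(
        np.log2(m.values + 1.0), m.detect_mask.copy(), state="log2"
    )


def replace_nondetected(m: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each non-detected cell by the gene's minimal detected value.

    Cohort-scoped: the minimum is taken per gene across all samples in the
    matrix.  The mask is cleared afterwards.  A gene with no detected value
    at all has no defined floor and is an error.
    """
    mask = m.detect_mask.to_numpy()
    vals = m.values.to_numpy().copy()
    n_detected = mask.sum(axis=1)
    if (n_detected == 0).any():
        bad = [g for g, n in zip(m.gene_ids, n_detected) if n == 0]
        raise ValueError(f"genes with no detected values: {bad}")
    with np.errstate(invalid="ignore"):
        floors = np.where(mask, vals, np.inf).min(axis=1)
    vals = np.where(mask, vals, floors[:, None])
    values = pd.DataFrame(vals, index=m.values.index, columns=m.values.columns)
    full = pd.DataFrame(True, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values, full, state=m.state)


def standardize_by_median(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's cohort median.

    Requires log2 state with all non-detected values already replaced.
    Accepts an already-standardized matrix too, where it is a no-op up to
    floating point (per-gene medians are already zero) — this makes the
    operation idempotent.
    """
    if m.state not in {"log2", "standardized"}:
        raise ExpressionStateError(
            f"standardize_by_median requires log2, matrix is {m.state}"
        )
    if not m.detect_mask.to_numpy().all():
        raise ValueError(
            "non-detected values must be replaced before standardization"
        )
    med = m.values.median(axis=1)
    values = m.values.sub(med, axis=0)
    return ExpressionMatrix(values, m.detect_mask.copy(), state="standardized")
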