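"""Expression-matrix container and the log10 / quantile / centralize pipeline.

The whole downstream analysis assumes centralized log10 expression: every
gene's values are differences from its cohort-mean log expression, so
positive values mean over-expression and negative values under-expression
relative to the cohort.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Allowed values of the scale flag, in pipeline order.
SCALES = ("raw", "log10", "centralized")


class ExpressionMatrix:
    """A genes x samples expression matrix with an explicit scale flag.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (index = gene IDs), samples in columns. Must be
        numeric, finite, with unique row and column labels.
    scale : str
        One of ``"raw"``, ``"log10"``, ``"centralized"``.
    """

    def __init__(self, values: pd.DataFrame, scale: str = "raw"):
        if scale not in SCALES:
            raise ValueError(f"unknown scale {scale!r}; expected one of {SCALES}")
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        arr = values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            g, s = np.argwhere(np.isnan(arr))[0]
            raise ValueError(
                f"missing value at gene {values.index[g]!r}, sample {values.columns[s]!r}; "
                "missing values are not permitted"
            )
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite value at gene {values.index[g]!r}, sample {values.columns[s]!r}"
            )
        self.values = values.astype(float)
        self.scale = scale

    # -- basic introspection -------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        g, s = self.shape
        return f"<ExpressionMatrix {g} genes x {s} samples, scale={self.scale!r}>"

    # -- I/O -----------------------------------------------------------------
    @classmethod
    def from_tsv(cls, path, scale: str = "raw") -> "ExpressionMatrix":
        """Read a tab-separated matrix: first column gene IDs, header sample IDs."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        try:
            return cls(df, scale=scale)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = out.index.name or "gene"
        out.to_csv(path, sep="\t", float_format="%.10g")


def log10_transform(matrix: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Elementwise ``log10(value + offset)``.

    Every shifted value must be strictly positive; the first offending
    gene/sample pair is named in the error.
    """
    arr = matrix.values.to_numpy() + offset
    if (arr <= 0).any():
        g, s = np.argwhere(arr <= 0)[0]
        raise ValueError(
            f"log10 undefined for gene {matrix.genes[g]!r}, sample {matrix.samples[s]!r} "
            f"(value + offset = {arr[g, s]:g} <= 0); increase --log10-offset"
        )
    out = pd.DataFrame(np.log10(arr), index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(out, scale="log10")


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample (column) onto the common distribution of rank means.

    The reference distribution is the mean over samples of the column-sorted
    values. Ties within a column receive the mean of the reference values at
    their tied ranks, so tied entries stay tied afterwards.
    """
    arr = matrix.values.to_numpy()
    n_genes, n_samples = arr.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    order = np.argsort(arr, axis=0, kind="stable")
    reference = np.sort(arr, axis=0).mean(axis=1)

    out = np.empty_like(arr)
    for j in range(n_samples):
        col = arr[:, j]
        idx = order[:, j]
        sorted_col = col[idx]
        mapped = reference.copy()
        # average the reference over runs of tied values
        start = 0
        for end in range(1, n_genes + 1):
            if end == n_genes or sorted_col[end] != sorted_col[start]:
                if end - start > 1:
                    mapped[start:end] = reference[start:end].mean()
                start = end
        out[idx, j] = mapped
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(df, scale=matrix.scale)


def centralize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's mean across samples; idempotent."""
    arr = matrix.values.to_numpy()
    out = arr - arr.mean(axis=1, keepdims=True)
    df = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(df, scale="centralized")


def preprocess(
    matrix: ExpressionMatrix,
    log10_offset: float = 0.0,
    skip: tuple[str, ...] = (),
) -> ExpressionMatrix:
    """Run log10 -> quantile normalization -> centralization.

    ``skip`` may contain ``"log10"`` and/or ``"qnorm"`` for input that is
    already log-scaled and/or normalized (the usual situation for
    preprocessed public array data).
    """
    unknown = set(skip) - {"log10", "qnorm"}
    if unknown:
        raise ValueError(f"unknown skip steps: {sorted(unknown)}")
    out = matrix
    if "log10" not in skip:
        out = log10_transform(out, offset=log10_offset)
    elif out.scale == "raw":
        out = ExpressionMatrix(out.values, scale="log10")
    if "qnorm" not in skip:
        out = quantile_normalize(out)
    return centralize(out)
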