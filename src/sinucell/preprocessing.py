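"""Input normalization for the sinusoidal autoencoder.

The model consumes a cells-by-genes matrix that has been log-transformed and
per-gene standardized (z-scored), so that every gene contributes on the same
scale to the reconstruction loss. Genes are deliberately not filtered:
stochastically expressed genes fit the periodic model poorly and receive
near-zero weight in the decoder, so they are effectively self-silencing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Valid values for :attr:`ExpressionMatrix.scale`.
SCALES = ("counts", "tpm", "log", "standardized", "corrected")


@dataclass
class ExpressionMatrix:
    """A cells × genes expression matrix with identifiers and scale state.

    Parameters
    ----------
    values
        Numeric matrix, one row per cell, one column per gene.
    cell_ids, gene_ids
        Unique string identifiers for rows and columns.
    scale
        One of ``counts``, ``tpm``, ``log``, ``standardized``, ``corrected``.
        ``corrected`` marks data on the standardized scale after subtraction
        of a fitted periodic component.
    gene_means, gene_sds
        Per-gene location/scale recorded by :func:`standardize_genes`, used to
        map corrected data back to the log scale. ``None`` otherwise.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    scale: str
    gene_means: np.ndarray | None = field(default=None, repr=False)
    gene_sds: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"values must be 2-D, got shape {self.values.shape}")
        self.cell_ids = [str(c) for c in self.cell_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        n, g = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell_ids for {n} rows")
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene_ids for {g} columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids are not unique")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids are not unique")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain NaN or Inf entries")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return replace(
            self,
            values=self.values.copy(),
            cell_ids=list(self.cell_ids),
            gene_ids=list(self.gene_ids),
            gene_means=None if self.gene_means is None else self.gene_means.copy(),
            gene_sds=None if self.gene_sds is None else self.gene_sds.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


def log_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """Apply ``log2(x + pseudocount)`` elementwise.

    Accepts raw counts or TPM; refuses matrices already on the log or
    standardized scale. Negative entries are rejected with the offending
    cell/gene named.
    """
    if m.scale not in ("counts", "tpm"):
        raise ValueError(f"log_transform expects counts or tpm input, got scale {m.scale!r}")
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    neg = np.argwhere(m.values < 0)
    if neg.size:
        i, j = neg[0]
        raise ValueError(
            f"negative expression value {m.values[i, j]} at cell {m.cell_ids[i]!r}, "
            f"gene {m.gene_ids[j]!r}"
        )
    return ExpressionMatrix(
        values=np.log2(m.values + pseudocount),
        cell_ids=list(m.cell_ids),
        gene_ids=list(m.gene_ids),
        scale="log",
    )


def standardize_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-score each gene column: mean 0, population standard deviation 1.

    Constant genes cannot be scaled and are mapped to all-zero columns (they
    then contribute nothing to the model loss); their identifiers are logged.
    The per-gene means and sds are stored on the result so a later correction
    step can be mapped back to the log scale.
    """
    if m.scale != "log":
        raise ValueError(f"standardize_genes expects log-scale input, got {m.scale!r}")
    if m.n_cells < 2:
        raise ValueError("standardization needs at least 2 cells")
    means = m.values.mean(axis=0)
    sds = m.values.std(axis=0)  # population sd, divisor N
    constant = sds == 0
    if constant.any():
        names = [g for g, c in zip(m.gene_ids, constant) if c]
        logger.info(
            "standardize_genes: %d constant gene(s) set to zero columns: %s",
            len(names), ", ".join(names[:20]) + ("..." if len(names) > 20 else ""),
        )
    safe_sds = np.where(constant, 1.0, sds)
    values = (m.values - means) / safe_sds
    values[:, constant] = 0.0
    return ExpressionMatrix(
        values=values,
        cell_ids=list(m.cell_ids),
        gene_ids=list(m.gene_ids),
        scale="standardized",
        gene_means=means,
        gene_sds=sds,
    )


def qc_filter_cells(
    m: ExpressionMatrix,
    min_total: float = 0.0,
    max_mito_fraction: float = 1.0,
    mito_prefix: str = "MT-",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Remove low-quality cells by total signal and mitochondrial fraction.

    Intended for droplet data; a cell is dropped if its total signal is below
    ``min_total`` or the fraction of signal on genes whose ID starts with
    ``mito_prefix`` exceeds ``max_mito_fraction``. Genes are never filtered.

    Returns the filtered matrix and a per-removed-cell report with columns
    ``cell_id``, ``total``, ``mito_fraction``, ``reason``.
    """
    if m.scale not in ("counts", "tpm"):
        raise ValueError(f"qc_filter_cells expects counts or tpm input, got scale {m.scale!r}")
    if not 0.0 <= max_mito_fraction <= 1.0:
        raise ValueError("max_mito_fraction must lie in [0, 1]")
    totals = m.values.sum(axis=1)
    mito_cols = np.array([g.startswith(mito_prefix) for g in m.gene_ids])
    mito_totals = m.values[:, mito_cols].sum(axis=1) if mito_cols.any() else np.zeros(m.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, mito_totals / totals, 0.0)
    low = totals < min_total
    mito_high = mito_frac > max_mito_fraction
    keep = ~(low | mito_high)
    if not keep.any():
        raise ValueError("qc_filter_cells removed every cell; thresholds too strict")
    removed = []
    for i in np.flatnonzero(~keep):
        reasons = []
        if low[i]:
            reasons.append("low_total")
        if mito_high[i]:
            reasons.append("high_mito")
        removed.append(
            {"cell_id": m.cell_ids[i], "total": totals[i],
             "mito_fraction": mito_frac[i], "reason": "+".join(reasons)}
        )
    report = pd.DataFrame(removed, columns=["cell_id", "total", "mito_fraction", "reason"])
    filtered = ExpressionMatrix(
        values=m.values[keep],
        cell_ids=[c for c, k in zip(m.cell_ids, keep) if k],
        gene_ids=list(m.gene_ids),
        scale=m.scale,
    )
    if len(removed):
        logger.info("qc_filter_cells removed %d of %d cells", len(removed), m.n_cells)
    return filtered, report
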