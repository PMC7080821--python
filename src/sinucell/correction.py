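"""Removal of the inferred periodic component from expression data.

The periodic process is assumed to act additively on log-scale expression,
so the fitted circular reconstruction ``ŷ^(circular)`` is an estimate of the
per-cell periodic effect and can be subtracted. The linear components of the
embedding model non-periodic structure and are deliberately left in the
data. A PCA-subtraction baseline (remove designated principal components) is
provided for comparison.
"""

from __future__ import annotations

import numpy as np

from .core_model import FittedModel, encode, decode
from .preprocessing import ExpressionMatrix


def _check_genes(m: ExpressionMatrix, model: FittedModel) -> None:
    if list(m.gene_ids) != list(model.gene_ids):
        raise ValueError("matrix and model gene sets differ (order-sensitive)")


def circular_component(model: FittedModel, m: ExpressionMatrix) -> np.ndarray:
    """The N × G periodic part of the reconstruction,
    ``V_circular · [cos x; sin x]`` per cell."""
    _check_genes(m, model)
    circ, lin = encode(m.values, model.encoder)
    y_circ, _ = decode(circ, lin, model.decoder, return_parts=True)
    return y_circ


def remove_circular(
    m: ExpressionMatrix, model: FittedModel, destandardize: bool = False
) -> ExpressionMatrix:
    """Subtract the fitted periodic component from the matrix.

    Exactly additive: output values + :func:`circular_component` equal the
    input to machine precision. The operation consumes a fitted model and
    never refits, so applying it twice subtracts the component twice.

    With ``destandardize`` the corrected values are mapped back to the log
    scale using the per-gene means/sds stored at standardization time.
    """
    _check_genes(m, model)
    corrected = m.values - circular_component(model, m)
    if destandardize:
        if m.gene_means is None or m.gene_sds is None:
            raise ValueError("matrix carries no standardization record to invert")
        sds = np.where(m.gene_sds == 0, 1.0, m.gene_sds)
        return ExpressionMatrix(
            values=corrected * sds + m.gene_means,
            cell_ids=list(m.cell_ids),
            gene_ids=list(m.gene_ids),
            scale="log",
        )
    return ExpressionMatrix(
        values=corrected,
        cell_ids=list(m.cell_ids),
        gene_ids=list(m.gene_ids),
        scale="corrected",
        gene_means=None if m.gene_means is None else m.gene_means.copy(),
        gene_sds=None if m.gene_sds is None else m.gene_sds.copy(),
    )


def remove_pcs(m: ExpressionMatrix, pc_indices) -> ExpressionMatrix:
    """Subtract the reconstruction built from designated principal components.

    ``pc_indices`` are 1-based (PC 1 is the leading component). The selected
    components are back-transformed to expression space and subtracted; the
    residual is orthogonal to the removed loading vectors.
    """
    idx = np.asarray(sorted(set(int(i) for i in pc_indices)), dtype=int)
    r = min(m.values.shape)
    if idx.size == 0:
        raise ValueError("no principal components designated")
    if idx.min() < 1 or idx.max() > r:
        raise ValueError(f"PC indices must lie in [1, {r}], got {idx.tolist()}")
    u, s, vt = np.linalg.svd(m.values, full_matrices=False)
    sel = idx - 1
    component = (u[:, sel] * s[sel]) @ vt[sel]
    return ExpressionMatrix(
        values=m.values - component,
        cell_ids=list(m.cell_ids),
        gene_ids=list(m.gene_ids),
        scale="corrected" if m.scale in ("standardized", "corrected") else m.scale,
        gene_means=None if m.gene_means is None else m.gene_means.copy(),
        gene_sds=None if m.gene_sds is None else m.gene_sds.copy(),
    )
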