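"""Embedding-dimensionality selection by reconstruction-error comparison.

The model with one circular plus (k−1) linear components is compared against
rank-k PCA at each candidate k. The chosen k* is the largest k whose
relative MSE improvement over k−1 still exceeds a threshold — an elbow rule
on the autoencoder's own reconstruction error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_model import ModelConfig, decode, encode, fit
from .preprocessing import ExpressionMatrix


@dataclass
class DimScan:
    """Reconstruction MSE of model and PCA over candidate dimensionalities."""

    k_values: list[int]
    model_mse: list[float]
    pca_mse: list[float]
    k_star: int

    def __post_init__(self) -> None:
        if not (len(self.k_values) == len(self.model_mse) == len(self.pca_mse)):
            raise ValueError("k_values, model_mse, pca_mse must have equal length")


def pca_reconstruction_mse(m: ExpressionMatrix, k: int) -> float:
    """Per-entry mean squared error of the rank-k PCA reconstruction.

    Computed from the SVD of the (already gene-centered) standardized
    matrix; equals the sum of the discarded squared singular values divided
    by the number of matrix entries.
    """
    n, g = m.values.shape
    if not 1 <= k <= min(n, g):
        raise ValueError(f"k must lie in [1, {min(n, g)}], got {k}")
    s = np.linalg.svd(m.values, compute_uv=False)
    return float((s[k:] ** 2).sum() / (n * g))


def model_reconstruction_mse(m: ExpressionMatrix, model) -> float:
    """Per-entry MSE of the autoencoder reconstruction of ``m``."""
    circ, lin = encode(m.values, model.encoder)
    recon = decode(circ, lin, model.decoder)
    return float(np.mean((m.values - recon) ** 2))


def scan_dimensionality(
    m: ExpressionMatrix,
    k_max: int,
    config: ModelConfig | None = None,
    drop_threshold: float = 0.05,
) -> DimScan:
    """Fit models of increasing embedding dimensionality and pick k*.

    For each k in 1..k_max a model with one circular and (k−1) linear
    components is trained and its per-entry reconstruction MSE recorded next
    to the rank-k PCA MSE. k* is the largest k whose relative MSE drop from
    k−1 exceeds ``drop_threshold``; if no drop qualifies, k* = 1.
    Deterministic given ``config.seed``.
    """
    if k_max < 1:
        raise ValueError("k_max must be at least 1")
    config = config or ModelConfig()
    ks, model_mse, pca_mse = [], [], []
    for k in range(1, k_max + 1):
        cfg = replace(config, n_linear=k - 1, circular=True)
        model = fit(m, cfg)
        ks.append(k)
        model_mse.append(model_reconstruction_mse(m, model))
        pca_mse.append(pca_reconstruction_mse(m, k))
    k_star = 1
    for i in range(1, len(ks)):
        prev, cur = model_mse[i - 1], model_mse[i]
        if prev > 0 and (prev - cur) / prev > drop_threshold:
            k_star = ks[i]
    return DimScan(k_values=ks, model_mse=model_mse, pca_mse=pca_mse, k_star=k_star)
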