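"""Sinusoidal autoencoder for circular pseudo-time inference.

The model embeds each cell's standardized expression profile ``y_n`` (length
G) onto one circular coordinate plus an optional small number of linear
coordinates, and reconstructs the profile from that embedding:

* encoder: a two-hidden-layer perceptron with tanh activations produces the
  circular coordinate, ``x_circ = W3 · tanh(W2 · tanh(W1 y + b1) + b2)``; the
  linear coordinates are a plain projection ``x_lin = W_lin y``.
* decoder: the first layer applies cosine and sine to the circular
  coordinate, the second layer is linear:
  ``ŷ = V_circ [cos x_circ; sin x_circ] + V_lin x_lin``.

Because the decoder is sinusoidal in the circular coordinate, each gene g is
reconstructed as ``A_g cos(x_circ − φ_g)``: the network simultaneously
assigns a pseudo-time to every cell and a peak phase/amplitude to every gene.
Training minimizes the squared reconstruction error with L2 penalties on all
weight matrices, by Adam on analytic gradients. The model is identifiable
only up to a global rotation and reflection of the circle; downstream scoring
must align before comparing to ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .preprocessing import ExpressionMatrix

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


@dataclass
class ModelConfig:
    """Hyperparameters of the sinusoidal autoencoder.

    Attributes
    ----------
    encoder_widths
        Hidden tanh layer sizes of the circular encoder.
    n_linear
        Number of additional linear embedding components (0 = circle only).
    alpha
        L2 coefficient(s) for the encoder weight matrices. A scalar is
        broadcast to every encoder matrix (including the linear projection);
        a sequence must give one coefficient per matrix.
    beta
        L2 coefficient for the decoder matrix ``V = [V_circ V_lin]``.
    gene_weights
        Optional length-G non-negative weights applied per gene inside the
        squared reconstruction error, to emphasize prior-knowledge genes.
    lr_final_fraction
        The Adam step size decays exponentially from ``learning_rate`` to
        ``learning_rate * lr_final_fraction`` over the scheduled epochs;
        1.0 disables the decay.
    circular
        If False the circular pathway is removed entirely and the model is a
        plain linear autoencoder with ``n_linear`` components (useful as the
        PCA-equivalent limit).
    n_restarts
        Independent seeded fits; the one with the lowest final loss is kept.
    """

    encoder_widths: tuple[int, ...] = (30, 20)
    n_linear: int = 0
    alpha: float | tuple[float, ...] = 1e-3
    beta: float = 1e-4
    gene_weights: np.ndarray | None = None
    epochs: int = 500
    batch_size: int = 128
    learning_rate: float = 5e-3
    lr_final_fraction: float = 0.05
    seed: int = 0
    early_stop_tol: float = 1e-6
    early_stop_window: int = 50
    circular: bool = True
    n_restarts: int = 1

    def __post_init__(self) -> None:
        self.encoder_widths = tuple(int(w) for w in self.encoder_widths)
        if any(w < 1 for w in self.encoder_widths):
            raise ValueError("encoder widths must be positive")
        if self.n_linear < 0:
            raise ValueError("n_linear must be non-negative")
        if not self.circular and self.n_linear < 1:
            raise ValueError("a model without the circular pathway needs n_linear >= 1")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 < self.lr_final_fraction <= 1:
            raise ValueError("lr_final_fraction must lie in (0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.gene_weights is not None:
            self.gene_weights = np.asarray(self.gene_weights, dtype=float)
            if (self.gene_weights < 0).any():
                raise ValueError("gene_weights must be non-negative")
            if not (self.gene_weights > 0).any():
                raise ValueError("gene_weights needs at least one positive entry")

    def n_encoder_matrices(self) -> int:
        n = (len(self.encoder_widths) + 1) if self.circular else 0
        if self.n_linear > 0:
            n += 1
        return n

    def resolved_alpha(self) -> np.ndarray:
        n = self.n_encoder_matrices()
        if np.isscalar(self.alpha):
            return np.full(n, float(self.alpha))
        a = np.asarray(self.alpha, dtype=float)
        if a.size != n:
            raise ValueError(f"alpha has {a.size} entries for {n} encoder matrices")
        if (a < 0).any():
            raise ValueError("alpha coefficients must be non-negative")
        return a


@dataclass
class EncoderParams:
    """Weights of the encoder.

    ``W1, b1, W2, b2, W3_circular`` form the tanh perceptron ending in a
    single circular output row; ``W_linear`` (n_linear × G) is the linear
    projection, empty when the model has no linear components.
    """

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3_circular: np.ndarray
    W_linear: np.ndarray

    def __post_init__(self) -> None:
        if self.W3_circular.size and self.W3_circular.shape[0] != 1:
            raise ValueError("W3_circular must have exactly one output row")


@dataclass
class DecoderParams:
    """Decoder weights: V_circular is G × 2 (cosine and sine columns),
    V_linear is G × n_linear."""

    V_circular: np.ndarray
    V_linear: np.ndarray

    def __post_init__(self) -> None:
        if self.V_circular.size and self.V_circular.shape[1] != 2:
            raise ValueError("V_circular must have two columns (cos, sin)")


@dataclass
class FittedModel:
    config: ModelConfig
    encoder: EncoderParams
    decoder: DecoderParams
    loss_history: list[float]
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.loss_history:
            raise ValueError("loss_history must be non-empty")
        if not np.isfinite(self.loss_history[-1]):
            raise ValueError("final loss is not finite")


@dataclass
class PseudotimeResult:
    """Per-cell circular pseudo-time in [0, 2π) plus linear coordinates."""

    circular: np.ndarray
    linear: np.ndarray

    def __post_init__(self) -> None:
        if ((self.circular < 0) | (self.circular >= TWO_PI)).any():
            raise ValueError("circular pseudo-times must lie in [0, 2π)")


def _check_width(y: np.ndarray, expected: int) -> np.ndarray:
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[1] != expected:
        raise ValueError(f"expected {expected} gene columns, got {y.shape[1]}")
    return y


def encode(y: np.ndarray, enc: EncoderParams) -> tuple[np.ndarray, np.ndarray]:
    """Map expression rows to (circular scalar, linear vector) embeddings.

    Returns the raw (un-wrapped) circular coordinate, one per row, and the
    N × n_linear matrix of linear coordinates.
    """
    G = enc.W1.shape[1] if enc.W1.size else enc.W_linear.shape[1]
    y = _check_width(y, G)
    if enc.W1.size:
        h1 = np.tanh(y @ enc.W1.T + enc.b1)
        h2 = np.tanh(h1 @ enc.W2.T + enc.b2)
        circ = (h2 @ enc.W3_circular.T)[:, 0]
    else:
        circ = np.zeros(y.shape[0])
    linear = y @ enc.W_linear.T if enc.W_linear.size else np.zeros((y.shape[0], 0))
    return circ, linear


def decode(
    x_circular: np.ndarray,
    x_linear: np.ndarray,
    dec: DecoderParams,
    return_parts: bool = False,
):
    """Reconstruct expression from an embedding.

    ``ŷ = V_circ [cos x; sin x] + V_lin x_lin``. With ``return_parts`` the
    circular and linear addends are returned separately (their sum is ŷ).
    """
    x_circular = np.atleast_1d(np.asarray(x_circular, dtype=float))
    n = x_circular.shape[0]
    if dec.V_circular.size:
        cs = np.column_stack([np.cos(x_circular), np.sin(x_circular)])
        y_circ = cs @ dec.V_circular.T
    else:
        y_circ = np.zeros((n, dec.V_linear.shape[0]))
    if dec.V_linear.size:
        x_linear = np.atleast_2d(np.asarray(x_linear, dtype=float))
        if x_linear.shape != (n, dec.V_linear.shape[1]):
            raise ValueError(
                f"linear embedding shape {x_linear.shape} does not match "
                f"decoder expectation {(n, dec.V_linear.shape[1])}"
            )
        y_lin = x_linear @ dec.V_linear.T
    else:
        y_lin = np.zeros_like(y_circ)
    if return_parts:
        return y_circ, y_lin
    return y_circ + y_lin


def _encoder_matrices(enc: EncoderParams, config: ModelConfig) -> list[np.ndarray]:
    mats = [enc.W1, enc.W2, enc.W3_circular] if config.circular else []
    if config.n_linear > 0:
        mats.append(enc.W_linear)
    return mats


def loss(
    batch: np.ndarray,
    enc: EncoderParams,
    dec: DecoderParams,
    config: ModelConfig,
) -> float:
    """Training objective on a batch of standardized rows.

    Sum over cells of the (optionally gene-weighted) squared reconstruction
    error, plus ``Σ_i α_i ||W_i||_F² + β ||V||_F²``.
    """
    batch = np.atleast_2d(np.asarray(batch, dtype=float))
    if batch.shape[0] == 0:
        raise ValueError("loss needs a non-empty batch")
    circ, lin = encode(batch, enc)
    yhat = decode(circ, lin, dec)
    resid = batch - yhat
    w = config.gene_weights if config.gene_weights is not None else 1.0
    data_term = float(np.sum(w * resid**2))
    alphas = config.resolved_alpha()
    penalty = sum(
        a * float(np.sum(m**2)) for a, m in zip(alphas, _encoder_matrices(enc, config))
    )
    penalty += config.beta * (
        float(np.sum(dec.V_circular**2)) + float(np.sum(dec.V_linear**2))
    )
    return data_term + penalty


def _init_params(
    G: int, config: ModelConfig, rng: np.random.Generator
) -> tuple[EncoderParams, DecoderParams]:
    # small symmetric uniform init scaled by fan-in
    def u(rows: int, cols: int, fan_in: int) -> np.ndarray:
        s = 1.0 / np.sqrt(max(fan_in, 1))
        return rng.uniform(-s, s, size=(rows, cols))

    if config.circular:
        h1, h2 = config.encoder_widths
        enc = EncoderParams(
            W1=u(h1, G, G),
            b1=np.zeros(h1),
            W2=u(h2, h1, h1),
            b2=np.zeros(h2),
            # wider final layer so the initial circular coordinate spans a
            # usable arc of the circle instead of collapsing near zero
            W3_circular=u(1, h2, 1),
            W_linear=u(config.n_linear, G, G) if config.n_linear else np.zeros((0, G)),
        )
        Vc = u(G, 2, 2)
    else:
        enc = EncoderParams(
            W1=np.zeros((0, G)), b1=np.zeros(0), W2=np.zeros((0, 0)), b2=np.zeros(0),
            W3_circular=np.zeros((1, 0)),
            W_linear=u(config.n_linear, G, G),
        )
        Vc = np.zeros((G, 2))
    Vl = u(G, config.n_linear, max(config.n_linear, 1)) if config.n_linear else np.zeros((G, 0))
    return enc, DecoderParams(V_circular=Vc, V_linear=Vl)


def _grads(
    Y: np.ndarray,
    enc: EncoderParams,
    dec: DecoderParams,
    config: ModelConfig,
    alphas: np.ndarray,
) -> dict[str, np.ndarray]:
    """Analytic gradients of :func:`loss` with respect to every parameter."""
    w = config.gene_weights if config.gene_weights is not None else None
    g = {}
    if config.circular:
        H1 = np.tanh(Y @ enc.W1.T + enc.b1)
        H2 = np.tanh(H1 @ enc.W2.T + enc.b2)
        t = (H2 @ enc.W3_circular.T)[:, 0]
        ct, st = np.cos(t), np.sin(t)
        C = np.column_stack([ct, st])
        Yhat = C @ dec.V_circular.T
    else:
        t = ct = st = C = H1 = H2 = None
        Yhat = np.zeros_like(Y)
    if config.n_linear:
        Xl = Y @ enc.W_linear.T
        Yhat = Yhat + Xl @ dec.V_linear.T
    dYhat = 2.0 * (Yhat - Y)
    if w is not None:
        dYhat = dYhat * w
    if config.circular:
        g["V_circular"] = dYhat.T @ C + 2.0 * config.beta * dec.V_circular
        dC = dYhat @ dec.V_circular
        dt = dC[:, 0] * (-st) + dC[:, 1] * ct
        g["W3_circular"] = dt[None, :] @ H2
        dH2 = dt[:, None] @ enc.W3_circular
        dZ2 = dH2 * (1.0 - H2**2)
        g["W2"] = dZ2.T @ H1
        g["b2"] = dZ2.sum(axis=0)
        dH1 = dZ2 @ enc.W2
        dZ1 = dH1 * (1.0 - H1**2)
        g["W1"] = dZ1.T @ Y
        g["b1"] = dZ1.sum(axis=0)
        a_iter = list(alphas)
        g["W1"] += 2.0 * a_iter[0] * enc.W1
        g["W2"] += 2.0 * a_iter[1] * enc.W2
        g["W3_circular"] += 2.0 * a_iter[2] * enc.W3_circular
    else:
        g["V_circular"] = np.zeros_like(dec.V_circular)
        g["W1"] = np.zeros_like(enc.W1)
        g["b1"] = np.zeros_like(enc.b1)
        g["W2"] = np.zeros_like(enc.W2)
        g["b2"] = np.zeros_like(enc.b2)
        g["W3_circular"] = np.zeros_like(enc.W3_circular)
    if config.n_linear:
        g["V_linear"] = dYhat.T @ Xl + 2.0 * config.beta * dec.V_linear
        dXl = dYhat @ dec.V_linear
        g["W_linear"] = dXl.T @ Y + 2.0 * float(alphas[-1]) * enc.W_linear
    else:
        g["V_linear"] = np.zeros_like(dec.V_linear)
        g["W_linear"] = np.zeros_like(enc.W_linear)
    return g


_PARAM_NAMES = ("W1", "b1", "W2", "b2", "W3_circular", "W_linear", "V_circular", "V_linear")


def _get_params(enc: EncoderParams, dec: DecoderParams) -> dict[str, np.ndarray]:
    return {
        "W1": enc.W1, "b1": enc.b1, "W2": enc.W2, "b2": enc.b2,
        "W3_circular": enc.W3_circular, "W_linear": enc.W_linear,
        "V_circular": dec.V_circular, "V_linear": dec.V_linear,
    }


def _fit_once(
    X: np.ndarray, config: ModelConfig, seed: int
) -> tuple[EncoderParams, DecoderParams, list[float]]:
    rng = np.random.default_rng(seed)
    N, G = X.shape
    enc, dec = _init_params(G, config, rng)
    params = _get_params(enc, dec)
    alphas = config.resolved_alpha()
    # Adam state
    mom = {k: np.zeros_like(v) for k, v in params.items()}
    vel = {k: np.zeros_like(v) for k, v in params.items()}
    b1m, b2m, eps = 0.9, 0.999, 1e-8
    step = 0
    batch = min(config.batch_size, N)
    history: list[float] = []
    for epoch in range(config.epochs):
        # exponential decay toward lr_final_fraction * learning_rate; a
        # constant step keeps Adam jittering around the optimum, which caps
        # reconstruction precision on clean data
        frac = epoch / max(config.epochs - 1, 1)
        lr = config.learning_rate * config.lr_final_fraction**frac
        order = rng.permutation(N)
        for start in range(0, N, batch):
            idx = order[start:start + batch]
            grads = _grads(X[idx], enc, dec, config, alphas)
            step += 1
            for k in _PARAM_NAMES:
                if params[k].size == 0:
                    continue
                gk = grads[k]
                mom[k] = b1m * mom[k] + (1 - b1m) * gk
                vel[k] = b2m * vel[k] + (1 - b2m) * gk**2
                mhat = mom[k] / (1 - b1m**step)
                vhat = vel[k] / (1 - b2m**step)
                params[k] -= lr * mhat / (np.sqrt(vhat) + eps)
        epoch_loss = loss(X, enc, dec, config)
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                "loss became non-finite during training; try a lower learning_rate"
            )
        history.append(epoch_loss)
        win = config.early_stop_window
        if config.early_stop_tol > 0 and len(history) > win:
            prev, cur = history[-win - 1], history[-1]
            if prev > 0 and abs(prev - cur) / prev < config.early_stop_tol:
                logger.debug("early stop at epoch %d", epoch + 1)
                break
    return enc, dec, history


def fit(m: ExpressionMatrix, config: ModelConfig | None = None) -> FittedModel:
    """Train the autoencoder on a standardized matrix.

    Deterministic for a fixed ``config.seed``. With ``config.n_restarts > 1``
    the fit is repeated from seeds ``seed, seed+1, ...`` and the run with the
    lowest final loss is returned (the loss surface has local optima where
    the circle is traversed more than once or collapses to an arc).
    """
    config = config or ModelConfig()
    if m.scale not in ("standardized", "corrected"):
        raise ValueError(f"fit expects a standardized matrix, got scale {m.scale!r}")
    if m.n_cells < 2:
        raise ValueError("fit needs at least 2 cells")
    X = m.values
    if not X.any():
        logger.warning("fitting an all-zero matrix; pseudo-times will be arbitrary")
    best: tuple[EncoderParams, DecoderParams, list[float]] | None = None
    for r in range(max(config.n_restarts, 1)):
        enc, dec, history = _fit_once(X, config, config.seed + r)
        if best is None or history[-1] < best[2][-1]:
            best = (enc, dec, history)
    enc, dec, history = best
    return FittedModel(
        config=config, encoder=enc, decoder=dec,
        loss_history=history, gene_ids=list(m.gene_ids),
    )


def pseudotime(model: FittedModel, m: ExpressionMatrix) -> PseudotimeResult:
    """Embed cells with a fitted model; circular coordinate wrapped to [0, 2π)."""
    if list(m.gene_ids) != list(model.gene_ids):
        for i, (a, b) in enumerate(zip(m.gene_ids, model.gene_ids)):
            if a != b:
                raise ValueError(
                    f"gene mismatch at position {i}: matrix has {a!r}, model has {b!r}"
                )
        raise ValueError(
            f"gene count mismatch: matrix has {len(m.gene_ids)}, "
            f"model has {len(model.gene_ids)}"
        )
    circ, lin = encode(m.values, model.encoder)
    wrapped = np.mod(circ, TWO_PI)
    wrapped[wrapped == TWO_PI] = 0.0  # guard against float round-up
    return PseudotimeResult(circular=wrapped, linear=lin)
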