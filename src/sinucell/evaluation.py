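"""Scoring utilities: stage classification, circular alignment, subclone
separability, cycling fraction, and gene-set program scores.

Discrete stage accuracy follows the convention of fitting a Gaussian mixture
on the one-dimensional pseudo-time and matching mixture components to truth
labels by the best bijection. Because the circular embedding is defined only
up to rotation and reflection, continuous comparisons go through
:func:`circular_alignment_score`, which searches both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import i0
from sklearn.manifold import TSNE
from sklearn.mixture import GaussianMixture

from .preprocessing import ExpressionMatrix

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


@dataclass
class StageAssignment:
    """Component labels from a mixture-model stage classifier."""

    labels: np.ndarray
    accuracy: float | None = None
    mapping: dict | None = None


def gmm_stage_assign(
    pseudotime: np.ndarray,
    n_components: int = 3,
    n_restarts: int = 5,
    seed: int = 0,
    truth=None,
) -> StageAssignment:
    """Cluster 1-D pseudo-times with a Gaussian mixture.

    The mixture is fitted on the raw pseudo-time values (not on circular
    coordinates). ``n_restarts`` independently initialized fits are run from
    seeds ``seed, seed+1, ...``; without ``truth`` the highest-likelihood
    fit is kept, with ``truth`` each restart is scored by
    :func:`best_match_accuracy` and the best accuracy is recorded (the usual
    convention for evaluating a stochastic clustering). A stage wrapping
    across 0/2π may split between components, which the restarts mitigate.
    Deterministic for fixed ``seed``.
    """
    t = np.asarray(pseudotime, dtype=float).reshape(-1, 1)
    if t.shape[0] < n_components:
        raise ValueError(f"need at least {n_components} cells")
    if np.ptp(t) == 0:
        raise ValueError("degenerate pseudo-times: all values identical")
    if truth is not None:
        truth = np.asarray(truth)
    best: StageAssignment | None = None
    best_key = -np.inf
    for r in range(max(n_restarts, 1)):
        gmm = GaussianMixture(
            n_components=n_components,
            n_init=1,
            init_params="random_from_data",
            random_state=seed + r,
            covariance_type="full",
        )
        labels = gmm.fit_predict(t)
        key = gmm.score(t) if truth is None else best_match_accuracy(labels, truth)
        if key > best_key:
            acc = None if truth is None else float(key)
            best = StageAssignment(labels=labels, accuracy=acc)
            best_key = key
    return best


def best_match_accuracy(pred, truth) -> float:
    """Fraction of cells correctly classified under the best bijective
    mapping of predicted components to true labels.

    Exhaustive over permutations for up to 5 labels, Hungarian assignment
    beyond that (both give the optimum). Unmatched components or truth
    classes (unequal cardinalities) simply count as wrong.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    n = pred.shape[0]
    pred_vals = sorted(set(pred.tolist()))
    truth_vals = sorted(set(truth.tolist()))
    conf = np.zeros((len(pred_vals), len(truth_vals)))
    pi = {v: i for i, v in enumerate(pred_vals)}
    ti = {v: i for i, v in enumerate(truth_vals)}
    for p, t in zip(pred, truth):
        conf[pi[p], ti[t]] += 1
    if max(len(pred_vals), len(truth_vals)) <= 5:
        k = len(pred_vals)
        best = 0.0
        # assign each predicted component an injective choice of truth labels
        for perm in permutations(range(len(truth_vals)), min(k, len(truth_vals))):
            hit = sum(conf[i, j] for i, j in enumerate(perm))
            best = max(best, hit)
    else:
        side = max(conf.shape)
        square = np.zeros((side, side))
        square[: conf.shape[0], : conf.shape[1]] = conf
        r, c = linear_sum_assignment(-square)
        best = square[r, c].sum()
    return float(best / n)


def circular_alignment_score(inferred, truth) -> tuple[float, float, bool]:
    """Agreement of two circular variables up to rotation and reflection.

    Embeds each angle vector as unit complex numbers and computes the
    absolute centered complex correlation, which maximizes the Pearson
    correlation of the cos/sin coordinates over all rotations in closed
    form; both orientations of ``inferred`` are tried. Returns
    ``(score, offset, reflected)`` where applying
    ``(±inferred + offset) mod 2π`` best matches ``truth``. Score is in
    [0, 1]; independent uniform angles give ~N^{-1/2}.
    """
    a = np.mod(np.asarray(truth, dtype=float), TWO_PI)
    b = np.mod(np.asarray(inferred, dtype=float), TWO_PI)
    if a.shape != b.shape:
        raise ValueError("inferred and truth must have equal length")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 cells")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant angle vector: alignment undefined")
    za = np.exp(1j * a)
    best = None
    for reflected in (False, True):
        zb = np.exp(1j * (-b if reflected else b))
        u = za - za.mean()
        v = zb - zb.mean()
        denom = np.sqrt((np.abs(u) ** 2).sum() * (np.abs(v) ** 2).sum())
        if denom == 0:
            raise ValueError("constant angle vector: alignment undefined")
        c = (u * np.conj(v)).sum() / denom
        score = float(np.abs(c))
        offset = float(np.mod(np.angle(c), TWO_PI))
        if best is None or score > best[0]:
            best = (score, offset, reflected)
    return best


def align_pseudotimes(inferred, offset: float, reflected: bool) -> np.ndarray:
    """Apply the transform found by :func:`circular_alignment_score`."""
    b = np.asarray(inferred, dtype=float)
    return np.mod((-b if reflected else b) + offset, TWO_PI)


def subclone_separability(
    m: ExpressionMatrix,
    clone_truth,
    seed: int = 0,
    perplexity: float = 30.0,
    n_restarts: int = 5,
) -> float:
    """Best two-component GMM classification accuracy of clone identity on a
    2-D t-SNE embedding of the matrix.

    The returned score depends on the embedding seed and perplexity, which
    are therefore explicit arguments; both are logged.
    """
    truth = np.asarray(clone_truth)
    if len(set(truth.tolist())) != 2:
        raise ValueError("subclone_separability needs exactly two clone labels")
    if m.n_cells < 10:
        raise ValueError("too few cells for a stable t-SNE embedding")
    logger.info("subclone_separability: t-SNE seed=%d perplexity=%.1f", seed, perplexity)
    emb = TSNE(
        n_components=2,
        perplexity=min(perplexity, (m.n_cells - 1) / 3.0),
        random_state=seed,
        init="pca",
    ).fit_transform(m.values)
    gmm = GaussianMixture(n_components=2, n_init=max(n_restarts, 1), random_state=seed)
    pred = gmm.fit_predict(emb)
    return best_match_accuracy(pred, truth)


def cycling_fraction(
    pseudotime,
    bandwidth: float = 0.3,
    gap_threshold: float = 0.2,
    grid_size: int = 720,
) -> tuple[float, list[tuple[float, float]]]:
    """Estimate the fraction of cells outside the densest pseudo-time arc.

    A von Mises kernel density (concentration ``1/bandwidth²``) is evaluated
    on a circular grid. Contiguous arcs where the density falls below
    ``gap_threshold`` times the circular mean density are "gaps" — stages
    absent from the sample. Cells in the single arc holding the most cells
    (the non-cycling bulk) are treated as resting; everything outside it is
    counted cycling. With no qualifying gap the sample is fully cycling and
    the fraction is 1.0. Returns ``(fraction, gap_arcs)``.
    """
    t = np.mod(np.asarray(pseudotime, dtype=float), TWO_PI)
    if t.shape[0] < 20:
        raise ValueError("need at least 20 cells for a density estimate")
    kappa = 1.0 / bandwidth**2
    grid = np.linspace(0.0, TWO_PI, grid_size, endpoint=False)
    dens = np.exp(kappa * np.cos(grid[:, None] - t[None, :])).mean(axis=1)
    dens /= TWO_PI * i0(kappa)
    low = dens < gap_threshold * dens.mean()
    if not low.any():
        return 1.0, []
    if low.all():
        return 0.0, [(0.0, TWO_PI)]
    # rotate so the grid starts inside a gap, then find contiguous runs
    start = int(np.argmax(low))
    rolled = np.roll(low, -start)
    arcs, gaps = [], []
    edges = np.flatnonzero(np.diff(rolled.astype(int)))
    bounds = np.concatenate([[0], edges + 1, [grid_size]])
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        seg = (
            grid[(lo + start) % grid_size],
            grid[(hi + start) % grid_size] if hi < grid_size else grid[start],
        )
        (gaps if rolled[lo] else arcs).append(seg)

    def count_in(arc):
        a, b = arc
        if b <= a:
            b += TWO_PI
        tt = np.where(t < a, t + TWO_PI, t)
        return int(((tt >= a) & (tt < b)).sum())

    occupancy = [count_in(arc) for arc in arcs]
    densest = int(np.argmax(occupancy))
    frac = 1.0 - occupancy[densest] / t.shape[0]
    return float(frac), gaps


def gene_set_score(m: ExpressionMatrix, gene_set) -> np.ndarray:
    """Per-cell mean expression over the genes of a program signature.

    Genes absent from the matrix are dropped; the intersection used is
    logged. Raises if no listed gene is present.
    """
    wanted = [g for g in gene_set if g in set(m.gene_ids)]
    if not wanted:
        raise ValueError("gene_set has empty intersection with the matrix genes")
    if len(wanted) < len(list(gene_set)):
        logger.info("gene_set_score: using %d of %d listed genes", len(wanted), len(list(gene_set)))
    col = {g: j for j, g in enumerate(m.gene_ids)}
    cols = np.array([col[g] for g in wanted], dtype=int)
    return m.values[:, cols].mean(axis=1)
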