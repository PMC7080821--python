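"""Synthetic data with circular ground truth, and virtual-tumor mixtures.

Two generators:

* :func:`simulate_circular` places cells on a circular trajectory in gene
  space: each periodic gene follows ``A_g cos(t_n − φ_g)`` over the cell's
  angular position ``t_n``, plus Gaussian noise; the remaining genes are pure
  noise. Discrete stage labels are assigned from contiguous pseudo-time arcs,
  mimicking cell-cycle stages (G0/G1, S, G2/M) as arcs of the circle.
* :func:`make_virtual_tumor` builds a two-clone mixture from a base
  population by resampling cells into a second clone and doubling the
  expression of chosen gene sets (a fold change applied on the linear scale,
  i.e. an additive ``log2(fold_change)`` shift of log-scale values), so clone
  identity is confounded with the shared periodic program.

Both are deterministic given their seed and return full ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocessing import ExpressionMatrix

TWO_PI = 2.0 * np.pi

#: default stage arcs: half the circle for G0/G1, quarters for S and G2/M
DEFAULT_ARCS = (("G0/G1", 0.0, np.pi), ("S", np.pi, 1.5 * np.pi), ("G2/M", 1.5 * np.pi, TWO_PI))


@dataclass
class CircularSimSpec:
    """Parameters of the circular-trajectory generator."""

    n_cells: int = 500
    n_genes: int = 200
    n_periodic_genes: int = 150
    amplitude_range: tuple[float, float] = (0.5, 2.0)
    noise_sd: float = 0.3
    stage_arcs: tuple[tuple[str, float, float], ...] = DEFAULT_ARCS
    pseudotime_distribution: str = "uniform"
    von_mises_modes: tuple[tuple[float, float, float], ...] = ((0.0, 2.0, 0.6), (np.pi, 2.0, 0.4))
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.n_periodic_genes <= self.n_genes:
            raise ValueError("need 0 <= n_periodic_genes <= n_genes")
        lo, hi = self.amplitude_range
        if not (0 < lo <= hi):
            raise ValueError("amplitude_range must be positive with lo <= hi")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.pseudotime_distribution not in ("uniform", "von_mises_mixture", "grid"):
            raise ValueError(f"unknown pseudotime_distribution {self.pseudotime_distribution!r}")
        arcs = sorted((float(a), float(b), str(lab)) for lab, a, b in self.stage_arcs)
        if not arcs or abs(arcs[0][0]) > 1e-12 or abs(arcs[-1][1] - TWO_PI) > 1e-9:
            raise ValueError("stage arcs must start at 0 and end at 2π")
        for (a0, b0, _), (a1, _, _) in zip(arcs, arcs[1:]):
            if abs(b0 - a1) > 1e-9:
                raise ValueError("stage arcs must be disjoint and cover [0, 2π)")


@dataclass
class CircularTruth:
    """Ground truth attached to a simulated matrix."""

    pseudotime: np.ndarray
    amplitudes: np.ndarray  # length n_genes; 0 for non-periodic genes
    phases: np.ndarray      # length n_genes; 0 for non-periodic genes
    stage_labels: list[str]
    periodic_mask: np.ndarray = field(default=None)


def _draw_pseudotimes(spec: CircularSimSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.pseudotime_distribution == "uniform":
        return rng.uniform(0.0, TWO_PI, size=spec.n_cells)
    if spec.pseudotime_distribution == "grid":
        # evenly spaced angles; empirical means of cos/sin vanish exactly, so
        # standardized sinusoidal columns are exactly representable
        return rng.permutation(np.arange(spec.n_cells) * TWO_PI / spec.n_cells)
    mus, kappas, weights = zip(*spec.von_mises_modes)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    comp = rng.choice(len(mus), size=spec.n_cells, p=weights)
    t = np.array([rng.vonmises(mus[c], kappas[c]) for c in comp])
    return np.mod(t, TWO_PI)


def stage_of(t: np.ndarray, arcs) -> list[str]:
    """Map angles to the label of the arc containing each one."""
    labels = []
    for ti in np.mod(np.asarray(t, dtype=float), TWO_PI):
        for lab, a, b in arcs:
            if a <= ti < b or (b >= TWO_PI - 1e-12 and ti >= a):
                labels.append(str(lab))
                break
        else:  # pragma: no cover - arcs validated to cover the circle
            raise ValueError(f"angle {ti} not covered by stage arcs")
    return labels


def simulate_circular(spec: CircularSimSpec) -> tuple[ExpressionMatrix, CircularTruth]:
    """Generate a log-scale matrix of cells on a circular trajectory.

    The first ``n_periodic_genes`` columns carry the sinusoidal program, the
    rest are pure noise. Values are treated as already log-scale (they are
    centered signals, not counts), so the matrix is flagged ``scale="log"``
    and feeds directly into per-gene standardization.
    """
    rng = np.random.default_rng(spec.seed)
    t = _draw_pseudotimes(spec, rng)
    amplitudes = np.zeros(spec.n_genes)
    phases = np.zeros(spec.n_genes)
    k = spec.n_periodic_genes
    amplitudes[:k] = rng.uniform(*spec.amplitude_range, size=k)
    phases[:k] = rng.uniform(0.0, TWO_PI, size=k)
    signal = amplitudes[None, :] * np.cos(t[:, None] - phases[None, :])
    signal[:, k:] = 0.0
    noise = rng.normal(0.0, spec.noise_sd, size=(spec.n_cells, spec.n_genes)) \
        if spec.noise_sd > 0 else np.zeros((spec.n_cells, spec.n_genes))
    values = signal + noise
    m = ExpressionMatrix(
        values=values,
        cell_ids=[f"cell_{i:05d}" for i in range(spec.n_cells)],
        gene_ids=[f"gene_{j:05d}" for j in range(spec.n_genes)],
        scale="log",
    )
    periodic = np.zeros(spec.n_genes, dtype=bool)
    periodic[:k] = True
    truth = CircularTruth(
        pseudotime=t, amplitudes=amplitudes, phases=phases,
        stage_labels=stage_of(t, spec.stage_arcs), periodic_mask=periodic,
    )
    return m, truth


@dataclass
class VirtualTumorSpec:
    """Parameters of the two-clone virtual-tumor construction.

    A second clone is sampled from the base population and a random set of
    ``n_cc_genes_perturbed`` genes from ``cc_gene_list`` plus
    ``n_other_genes_perturbed`` genes outside it get their expression
    multiplied by ``fold_change`` (default 2, i.e. doubled).
    """

    n_cells_clone2: int = 288
    n_cc_genes_perturbed: int = 600
    n_other_genes_perturbed: int = 1000
    cc_gene_list: tuple[str, ...] = ()
    fold_change: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_clone2 < 1:
            raise ValueError("clone 2 needs at least one cell")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")


def make_virtual_tumor(
    base: ExpressionMatrix, spec: VirtualTumorSpec
) -> tuple[ExpressionMatrix, np.ndarray, list[str]]:
    """Build a two-clone mixture by doubling gene sets in a resampled clone.

    Clone 1 is the base population unchanged; clone 2 is ``n_cells_clone2``
    cells sampled from it (with replacement when more cells are requested
    than available) with the selected genes shifted by ``+log2(fold_change)``
    on the log scale. Returns the row-concatenated matrix, integer clone
    labels (0/1), and the exact perturbed gene identifiers.
    """
    if base.scale != "log":
        raise ValueError(f"make_virtual_tumor expects a log-scale base matrix, got {base.scale!r}")
    rng = np.random.default_rng(spec.seed)
    gene_set = set(base.gene_ids)
    cc_avail = [g for g in spec.cc_gene_list if g in gene_set]
    other_avail = [g for g in base.gene_ids if g not in set(spec.cc_gene_list)]
    if len(cc_avail) < spec.n_cc_genes_perturbed:
        raise ValueError(
            f"need {spec.n_cc_genes_perturbed} cell-cycle genes but only "
            f"{len(cc_avail)} of the listed genes are present"
        )
    if len(other_avail) < spec.n_other_genes_perturbed:
        raise ValueError(
            f"need {spec.n_other_genes_perturbed} non-cell-cycle genes but only "
            f"{len(other_avail)} are available"
        )
    cc_pick = rng.choice(len(cc_avail), size=spec.n_cc_genes_perturbed, replace=False)
    other_pick = rng.choice(len(other_avail), size=spec.n_other_genes_perturbed, replace=False)
    perturbed = sorted(
        {cc_avail[i] for i in cc_pick} | {other_avail[i] for i in other_pick}
    )
    col = {g: j for j, g in enumerate(base.gene_ids)}
    cols = np.array([col[g] for g in perturbed], dtype=int)

    n = base.n_cells
    replace_rows = spec.n_cells_clone2 > n
    rows = rng.choice(n, size=spec.n_cells_clone2, replace=replace_rows)
    clone2 = base.values[rows].copy()
    clone2[:, cols] += np.log2(spec.fold_change)
    values = np.vstack([base.values, clone2])
    cell_ids = list(base.cell_ids) + [
        f"clone2_{i:05d}_{base.cell_ids[r]}" for i, r in enumerate(rows)
    ]
    mixed = ExpressionMatrix(
        values=values, cell_ids=cell_ids, gene_ids=list(base.gene_ids), scale="log"
    )
    labels = np.concatenate([np.zeros(n, dtype=int), np.ones(spec.n_cells_clone2, dtype=int)])
    return mixed, labels, perturbed


def synthetic_cell_cycle_gene_ids(n: int = 892, prefix: str = "gene") -> list[str]:
    """A synthetic stand-in list of 'known cell-cycle gene' identifiers.

    Purely positional (the first ``n`` generated gene IDs); real analyses
    should supply a curated cell-cycle gene list instead.
    """
    return [f"{prefix}_{j:05d}" for j in range(n)]
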