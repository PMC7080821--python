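"""Periodic marker-gene discovery from decoder weights.

By the identity ``a cos x + b sin x = A cos(x − φ)``, the two circular
decoder weights of gene g define its peak amplitude ``A_g = sqrt(a² + b²)``
and peak phase ``φ_g = atan2(b, a)``. Because the model is trained on
per-gene standardized data, A_g is a scale-free prominence of the periodic
pattern, comparable across genes and across separately fitted datasets;
genes are ranked by it. Phases inherit the model's global rotation and
reflection indeterminacy, amplitudes do not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import DecoderParams

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


@dataclass
class GenePeriodicity:
    """Per-gene amplitude A_g >= 0 and peak phase φ_g in [0, 2π)."""

    gene_ids: list[str]
    amplitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if not (len(self.gene_ids) == self.amplitude.size == self.phase.size):
            raise ValueError("gene_ids, amplitude, phase must have equal length")
        if (self.amplitude < 0).any():
            raise ValueError("amplitudes must be non-negative")
        if ((self.phase < 0) | (self.phase >= TWO_PI)).any():
            raise ValueError("phases must lie in [0, 2π)")


def gene_periodicity(dec: DecoderParams, gene_ids) -> GenePeriodicity:
    """Convert circular decoder rows to amplitude/phase form.

    A zero row maps to (A=0, φ=0) by convention.
    """
    v = dec.V_circular
    gene_ids = [str(g) for g in gene_ids]
    if v.shape[0] != len(gene_ids):
        raise ValueError(f"decoder has {v.shape[0]} gene rows but {len(gene_ids)} ids given")
    amplitude = np.hypot(v[:, 0], v[:, 1])
    phase = np.mod(np.arctan2(v[:, 1], v[:, 0]), TWO_PI)
    phase[amplitude == 0] = 0.0
    return GenePeriodicity(gene_ids=gene_ids, amplitude=amplitude, phase=phase)


def rank_markers(p: GenePeriodicity, top_n: int | None = None) -> pd.DataFrame:
    """Rank genes by amplitude, descending; ties broken by gene id.

    Returns a frame with columns ``gene_id, amplitude, phase, rank``. A
    ``top_n`` larger than the gene count is truncated with a warning.
    """
    if top_n is None:
        top_n = len(p.gene_ids)
    if top_n < 1:
        raise ValueError("top_n must be at least 1")
    if top_n > len(p.gene_ids):
        logger.warning("top_n=%d exceeds gene count %d; truncating", top_n, len(p.gene_ids))
        top_n = len(p.gene_ids)
    df = pd.DataFrame(
        {"gene_id": p.gene_ids, "amplitude": p.amplitude, "phase": p.phase}
    ).sort_values(
        ["amplitude", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df.head(top_n)


def wrap_to_pi(delta: np.ndarray) -> np.ndarray:
    """Wrap angle differences to the signed interval (−π, π]."""
    return np.pi - np.mod(np.pi - np.asarray(delta, dtype=float), TWO_PI)


def compare_conditions(p_a: GenePeriodicity, p_b: GenePeriodicity) -> pd.DataFrame:
    """Per-gene periodicity difference between two fitted conditions.

    Amplitudes from separately fitted models on standardized data are
    directly comparable; ``delta_A = A_a − A_b``. Phase differences are
    wrapped to (−π, π] so earlier/later peaks are signed — note they are
    only meaningful after the two fits have been rotationally aligned.
    Gene sets are intersected (reported via logging); the result is sorted
    by |delta_A| descending.
    """
    common = sorted(set(p_a.gene_ids) & set(p_b.gene_ids))
    if not common:
        raise ValueError("conditions share no genes")
    if len(common) < max(len(p_a.gene_ids), len(p_b.gene_ids)):
        logger.info("compare_conditions: intersected to %d shared genes", len(common))
    ia = {g: i for i, g in enumerate(p_a.gene_ids)}
    ib = {g: i for i, g in enumerate(p_b.gene_ids)}
    a_idx = np.array([ia[g] for g in common])
    b_idx = np.array([ib[g] for g in common])
    delta_a = p_a.amplitude[a_idx] - p_b.amplitude[b_idx]
    delta_phi = wrap_to_pi(p_a.phase[a_idx] - p_b.phase[b_idx])
    df = pd.DataFrame(
        {
            "gene_id": common,
            "A_a": p_a.amplitude[a_idx],
            "A_b": p_b.amplitude[b_idx],
            "delta_A": delta_a,
            "delta_phase": delta_phi,
        }
    )
    order = np.argsort(-np.abs(df["delta_A"].to_numpy()), kind="mergesort")
    return df.iloc[order].reset_index(drop=True)
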