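# sinucell

Circular pseudo-time inference and periodic-effect removal for single-cell
gene expression data.

Many biological processes are periodic — the cell cycle is the canonical
example: cells move through G0/G1 → S → G2/M and back, so a proliferating
population traces a **closed loop** in gene-expression space. Linear
factorizations (PCA, NMF, ICA) need two or more components to describe a
loop and cannot assign a meaningful one-dimensional timing to cells on it.
`sinucell` fits the loop directly with a sinusoidal autoencoder, yielding

* a circular **pseudo-time** `x_n ∈ [0, 2π)` for every cell,
* a per-gene **amplitude `A_g` and peak phase `φ_g`** describing how
  strongly and when each gene peaks over the cycle, and
* a **corrected expression matrix** with the periodic program subtracted —
  useful when the cell cycle confounds the structure you actually care
  about (tumor subclones, cell types, differentiation).

The package is aimed at computational biologists analyzing scRNA-seq (or
bulk/qPCR) expression matrices who need cell-cycle staging, cycle-effect
removal, or discovery of genes tracking any circular process.

## Model

Each cell's standardized expression profile **y**_n (G genes) is encoded to
one circular coordinate by a tanh perceptron and decoded through cosine and
sine:

```
x_n = W3 · tanh(W2 · tanh(W1 y_n + b1) + b2)          (+ optional linear part W_lin y_n)
ŷ_n = V_circ · [cos x_n ; sin x_n] + V_lin · x_lin
```

Training minimizes `Σ_n ||y_n − ŷ_n||² + Σ_i α_i ||W_i||² + β ||V||²` with
Adam on analytic gradients (CPU, pure numpy). Because the decoder is
sinusoidal, gene g is reconstructed as `A_g cos(x_n − φ_g)` with
`A_g = √(V_g,cos² + V_g,sin²)` and `φ_g = atan2(V_g,sin, V_g,cos)` — the
fit simultaneously times every cell and assigns every gene a peak phase and
amplitude. The solution is identifiable only up to a rotation and
reflection of the circle; all comparisons against ground truth go through
an alignment step (`circular_alignment_score`).

Subtracting the circular part of the reconstruction (`remove_circular`)
removes the periodic program while leaving everything else — including any
optional linear embedding components — in the data.

## Worked example

```python
import numpy as np
from sinucell import (
    CircularSimSpec, ModelConfig, circular_alignment_score, fit,
    gene_periodicity, pseudotime, rank_markers, remove_circular,
    simulate_circular, standardize_genes,
)

# 300 cells on a noisy circular trajectory; 80 of 120 genes are periodic
matrix, truth = simulate_circular(
    CircularSimSpec(n_cells=300, n_genes=120, n_periodic_genes=80,
                    noise_sd=0.3, seed=42)
)
m = standardize_genes(matrix)

model = fit(m, ModelConfig(seed=0))
result = pseudotime(model, m)

score, offset, reflected = circular_alignment_score(
    result.circular, truth.pseudotime
)
print(f"alignment with generating angles: {score:.3f} "
      f"(offset {offset:.2f} rad, reflected={reflected})")

markers = rank_markers(gene_periodicity(model.decoder, model.gene_ids), top_n=3)
print(markers.to_string(index=False))

corrected = remove_circular(m, model)
periodic = truth.periodic_mask
print(f"sd of periodic genes before/after correction: "
      f"{m.values[:, periodic].std():.2f} / "
      f"{corrected.values[:, periodic].std():.2f}")
```

Output:

```
alignment with generating angles: 0.999 (offset 6.20 rad, reflected=True)
   gene_id  amplitude    phase  rank
gene_00019   1.438800 3.423675     1
gene_00039   1.435170 0.482220     2
gene_00033   1.429272 0.553841     3
sd of periodic genes before/after correction: 1.00 / 0.36
```

The inferred pseudo-times match the generating angles almost perfectly
(score 1 = identical up to rotation/reflection; independent angles score
near 0). The top-ranked markers are periodic genes with the largest fitted
amplitudes, and subtracting the circular component removes about 87% of
the periodic genes' variance (sd 1.00 → 0.36; what remains is mostly the
simulation's additive noise).

The same pipeline is available from the shell:

```
sinucell simulate circular --out sim.csv --truth-out truth.csv --seed 0
sinucell fit sim.csv --out model.json --seed 0
sinucell pseudotime sim.csv --model model.json --out pt.csv
sinucell remove sim.csv --model model.json --out corrected.csv
sinucell markers --model model.json --out markers.tsv
sinucell evaluate stages pt.csv --truth truth.csv --out accuracy.json
```

## Layout

| module | contents |
| --- | --- |
| `sinucell.preprocessing` | `ExpressionMatrix`, log transform, per-gene standardization, cell QC |
| `sinucell.core_model` | the sinusoidal autoencoder: `fit`, `encode`/`decode`, `pseudotime` |
| `sinucell.model_selection` | embedding-dimensionality scan against PCA |
| `sinucell.correction` | `remove_circular`, PCA-subtraction baseline |
| `sinucell.markers` | amplitude/phase per gene, marker ranking, condition comparison |
| `sinucell.simulator` | circular-trajectory generator, virtual-tumor two-clone mixtures |
| `sinucell.evaluation` | GMM staging, best-match accuracy, circular alignment, t-SNE separability, cycling fraction, gene-set scores |
| `sinucell.io` / `sinucell.cli` | CSV/TSV/MatrixMarket readers and writers, model archive, `sinucell` command |

See `docs/methods.md` for the modeling assumptions, parameter defaults, and
known limitations.
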