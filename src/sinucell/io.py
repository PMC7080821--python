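"""Readers and writers for expression matrices, model archives, and results.

Supported matrix dialects:

* dense CSV/TSV — header row of gene IDs, first column of cell IDs
  (``genes_in_rows`` transposes after reading);
* MatrixMarket coordinate — ``matrix.mtx`` with ``barcodes.tsv`` and
  ``features.tsv``/``genes.tsv`` sidecars in the same directory, following
  the 10x convention of genes in rows (transposed on read).

The model archive is a single JSON file holding the configuration, every
parameter array, and the gene universe; the round trip is bit-exact because
floats survive JSON via their shortest-repr decimal form.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .core_model import DecoderParams, EncoderParams, FittedModel, ModelConfig
from .preprocessing import ExpressionMatrix


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".mtx":
        return "mtx"
    if suffix == ".tsv":
        return "tsv"
    return "csv"


def read_matrix(
    path: str | Path,
    dialect: str | None = None,
    genes_in_rows: bool = False,
    scale: str = "counts",
) -> ExpressionMatrix:
    """Read an expression matrix; ``scale`` declares the units of the values.

    For MTX, ``path`` is the ``.mtx`` file and the barcode/feature sidecars
    are located next to it; the 10x genes-in-rows orientation is assumed and
    transposed, so ``genes_in_rows`` is ignored for this dialect.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input matrix not found: {path}")
    dialect = dialect or _infer_dialect(path)
    if dialect == "mtx":
        raw = mmread(path)
        mat = raw.toarray() if hasattr(raw, "toarray") else np.asarray(raw)
        folder = path.parent
        barcodes = _read_ids(folder / "barcodes.tsv")
        feat_path = folder / "features.tsv"
        if not feat_path.exists():
            feat_path = folder / "genes.tsv"
        genes = _read_ids(feat_path)
        values = mat.T  # 10x: genes in rows, cells in columns
        return ExpressionMatrix(values=values, cell_ids=barcodes, gene_ids=genes, scale=scale)
    if dialect in ("csv", "tsv"):
        sep = "," if dialect == "csv" else "\t"
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split(sep)[1:]
        if len(set(header)) != len(header):
            raise ValueError(f"{path}: header gene IDs are not unique")
        df = pd.read_csv(path, sep=sep, index_col=0)
        if genes_in_rows:
            df = df.T
        return ExpressionMatrix(
            values=df.to_numpy(dtype=float),
            cell_ids=[str(i) for i in df.index],
            gene_ids=[str(c) for c in df.columns],
            scale=scale,
        )
    raise ValueError(f"unknown dialect {dialect!r}; expected csv, tsv, or mtx")


def _read_ids(path: Path) -> list[str]:
    if not path.exists():
        raise FileNotFoundError(f"MTX sidecar not found: {path}")
    ids = []
    for line in path.read_text().splitlines():
        if line.strip():
            ids.append(line.split("\t")[0].strip())
    return ids


def write_matrix(
    m: ExpressionMatrix,
    path: str | Path,
    dialect: str | None = None,
    genes_in_rows: bool = False,
) -> None:
    """Write a matrix in CSV/TSV or MatrixMarket (+sidecars) form."""
    path = Path(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "mtx":
        folder = path.parent
        folder.mkdir(parents=True, exist_ok=True)
        mmwrite(path, csr_matrix(m.values.T))  # genes in rows, 10x style
        (folder / "barcodes.tsv").write_text("\n".join(m.cell_ids) + "\n")
        (folder / "features.tsv").write_text("\n".join(m.gene_ids) + "\n")
        return
    sep = "," if dialect == "csv" else "\t"
    df = m.to_frame()
    if genes_in_rows:
        df = df.T
    df.to_csv(path, sep=sep)


def _encode_array(a: np.ndarray) -> dict:
    return {"shape": list(a.shape), "data": a.ravel().tolist()}


def _decode_array(d: dict) -> np.ndarray:
    return np.asarray(d["data"], dtype=float).reshape(d["shape"])


def save_model(model: FittedModel, path: str | Path) -> None:
    """Serialize a fitted model (config + parameters + gene ids) to JSON."""
    cfg = dataclasses.asdict(model.config)
    if cfg["gene_weights"] is not None:
        cfg["gene_weights"] = np.asarray(cfg["gene_weights"]).tolist()
    payload = {
        "format": "sinucell-model",
        "version": 1,
        "config": cfg,
        "encoder": {k: _encode_array(v) for k, v in dataclasses.asdict(model.encoder).items()},
        "decoder": {k: _encode_array(v) for k, v in dataclasses.asdict(model.decoder).items()},
        "loss_history": model.loss_history,
        "gene_ids": model.gene_ids,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> FittedModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "sinucell-model":
        raise ValueError(f"{path} is not a sinucell model archive")
    cfg = payload["config"]
    for key in ("encoder_widths", "alpha"):
        if isinstance(cfg[key], list):
            cfg[key] = tuple(cfg[key])
    if cfg["gene_weights"] is not None:
        cfg["gene_weights"] = np.asarray(cfg["gene_weights"], dtype=float)
    return FittedModel(
        config=ModelConfig(**cfg),
        encoder=EncoderParams(**{k: _decode_array(v) for k, v in payload["encoder"].items()}),
        decoder=DecoderParams(**{k: _decode_array(v) for k, v in payload["decoder"].items()}),
        loss_history=list(payload["loss_history"]),
        gene_ids=list(payload["gene_ids"]),
    )


def write_pseudotime(result, cell_ids, path: str | Path) -> None:
    """Write per-cell pseudo-time (and linear coordinates) as CSV."""
    cols = {"cell_id": list(cell_ids), "pseudotime": result.circular}
    for j in range(result.linear.shape[1]):
        cols[f"linear_{j + 1}"] = result.linear[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g")


def write_phenotype(result, path: str | Path, name: str = "pseudotime") -> None:
    """Write pseudo-time as a continuous-phenotype label file.

    One labeled numeric row, space-separated — the continuous class-label
    dialect consumed by external enrichment tools.
    """
    values = " ".join(f"{v:.6g}" for v in result.circular)
    Path(path).write_text(f"#numeric\n#{name}\n{values}\n")


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_provenance(path: str | Path, config: dict, inputs: list[str | Path]) -> None:
    """Record a machine-readable provenance stamp for a run."""
    import sinucell

    record = {
        "package": "sinucell",
        "version": sinucell.__version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "config": config,
        "inputs": {str(p): file_checksum(p) for p in inputs if Path(p).exists()},
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str))
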