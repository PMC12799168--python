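"""Readers/writers for expression matrices and annotation tables.

Formats: MatrixMarket triplet with sidecar gene/observation TSVs
(``mtx_dir``), or dense CSV with genes as rows (``csv``).  Annotation
tables are TSV with a header row.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import scipy.io as spio
import scipy.sparse as sp

from .core import COUNTS, LOGNORM, GeneExpressionMatrix, ValidationError, logger

_MTX = "matrix.mtx"
_GENES = "genes.tsv"
_OBS = "obs.tsv"


def read_matrix(path, format: str = "mtx_dir", layer_tag: str = COUNTS) -> GeneExpressionMatrix:
    """Load a genes x observations matrix from disk.

    ``mtx_dir``: a directory holding ``matrix.mtx`` (genes as rows),
    ``genes.tsv`` and ``obs.tsv``; the TSVs carry ids in their first
    column.  ``csv``: a dense table with gene ids as the row index and
    observation ids as column headers.
    """
    if format == "mtx_dir":
        for name in (_MTX, _GENES, _OBS):
            if not os.path.exists(os.path.join(path, name)):
                raise FileNotFoundError(f"missing {name} under {path}")
        values = np.asarray(spio.mmread(os.path.join(path, _MTX)).todense())
        genes = pd.read_csv(os.path.join(path, _GENES), sep="\t")
        obs = pd.read_csv(os.path.join(path, _OBS), sep="\t")
        gene_ids = genes.iloc[:, 0].astype(str).to_numpy()
        obs_ids = obs.iloc[:, 0].astype(str).to_numpy()
        obs_meta = obs.set_index(obs.columns[0])
        obs_meta.index.name = "obs_id"
        if values.shape != (len(gene_ids), len(obs_ids)):
            raise ValidationError(
                f"matrix shape {values.shape} does not match "
                f"{len(gene_ids)} genes x {len(obs_ids)} observations"
            )
        return GeneExpressionMatrix(values, gene_ids, obs_ids, obs_meta, layer_tag=layer_tag)
    if format == "csv":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        df = pd.read_csv(path, index_col=0)
        return GeneExpressionMatrix(
            df.to_numpy(),
            df.index.astype(str).to_numpy(),
            df.columns.astype(str).to_numpy(),
            layer_tag=layer_tag,
        )
    raise ValidationError(f"unknown format {format!r}")


def write_matrix(m: GeneExpressionMatrix, path, format: str = "mtx_dir") -> None:
    """Write a matrix in a form :func:`read_matrix` round-trips exactly.

    Counts round-trip bit-exactly; lognorm values to MatrixMarket's
    full double precision.
    """
    if format == "mtx_dir":
        os.makedirs(path, exist_ok=True)
        spio.mmwrite(
            os.path.join(path, _MTX),
            sp.coo_matrix(m.values),
            precision=None if m.layer_tag == COUNTS else 17,
        )
        pd.DataFrame({"gene_id": m.gene_ids}).to_csv(
            os.path.join(path, _GENES), sep="\t", index=False
        )
        meta = m.obs_meta.reset_index()
        meta.to_csv(os.path.join(path, _OBS), sep="\t", index=False)
    elif format == "csv":
        pd.DataFrame(m.values, index=m.gene_ids, columns=m.obs_ids).to_csv(path)
    else:
        raise ValidationError(f"unknown format {format!r}")


def normalize_lognorm(m: GeneExpressionMatrix, scale: float = 1e4, pseudocount: float = 1.0) -> GeneExpressionMatrix:
    """Library-size normalize to ``scale`` total per cell, then log2(x + pseudocount).

    Cells with zero total counts cannot be normalized and are dropped
    with a warning.  The output is invariant to scaling any single
    cell's counts by a positive constant.
    """
    if m.layer_tag != COUNTS:
        raise ValidationError("normalize_lognorm expects a counts layer")
    totals = m.values.sum(axis=0)
    keep = totals > 0
    if not keep.all():
        dropped = [str(o) for o in m.obs_ids[~keep]]
        logger.warning("dropping %d all-zero observation(s): %s", len(dropped), dropped[:5])
    sub = m.subset_obs(keep)
    norm = sub.values * (scale / totals[keep])
    out = sub.__class__(
        np.log2(norm + pseudocount),
        sub.gene_ids,
        sub.obs_ids,
        sub.obs_meta,
        layer_tag=LOGNORM,
    )
    return out


def read_assignment_table(path) -> pd.DataFrame:
    """Cell -> perturbation TSV with columns obs_id, tf, mode[, is_control]."""
    from .core import assignments_to_frame

    return assignments_to_frame(pd.read_csv(path, sep="\t"))


def write_lfc_table(lfc, path) -> None:
    """LFC vector as TSV (gene, lfc, mean_a, mean_b, detected)."""
    df = pd.DataFrame(
        {
            "gene": lfc.gene_ids,
            "lfc": lfc.lfc,
            "mean_a": lfc.mean_a if lfc.mean_a is not None else np.nan,
            "mean_b": lfc.mean_b if lfc.mean_b is not None else np.nan,
            "detected": lfc.detected_mask.astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_lfc_table(path, n_a: int = 0, n_b: int = 0, label: str = ""):
    """Inverse of :func:`write_lfc_table`."""
    from .diffexp import LFCVector

    df = pd.read_csv(path, sep="\t")
    if not {"gene", "lfc"}.issubset(df.columns):
        raise ValidationError("LFC table needs columns gene, lfc")
    detected = (
        df["detected"].astype(bool).to_numpy()
        if "detected" in df.columns
        else np.isfinite(df["lfc"].to_numpy(dtype=float))
    )
    return LFCVector(
        df["gene"].astype(str).to_numpy(),
        df["lfc"].to_numpy(dtype=float),
        n_a,
        n_b,
        detected,
        df["mean_a"].to_numpy(dtype=float) if "mean_a" in df.columns else None,
        df["mean_b"].to_numpy(dtype=float) if "mean_b" in df.columns else None,
        label=label or str(path),
    )


def read_tf_target_table(path) -> pd.DataFrame:
    """TF -> target TSV with columns tf, target[, weight]."""
    df = pd.read_csv(path, sep="\t")
    if not {"tf", "target"}.issubset(df.columns):
        raise ValidationError("TF target table needs columns tf, target")
    if "weight" not in df.columns:
        df["weight"] = 1.0
    return df
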