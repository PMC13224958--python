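"""Downstream products of a fitted model.

Three outputs: batch-corrected expression (in :mod:`.model`), continuous
differential-expression vector fields, and gene-program / regulon
activities.  The vector field evaluates, at every cell's latent position,
the per-gene expression shift induced by a unit change of a sample-level
covariate — differential expression along the cell-state continuum, with
no clustering step.
"""
from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import DecompositionModel

__all__ = ["VectorFieldResult", "de_vector_field", "program_activities", "integrated_embedding"]


@dataclasses.dataclass
class VectorFieldResult:
    """Per-cell, per-gene expression shifts for one covariate.

    ``shifts[:, n] = D_t b_n`` is the change in expected expression at cell
    n per unit increase of covariate t.  ``gene_scores`` aggregates each
    gene's shift magnitude (root mean square across the queried cells);
    ``cell_magnitudes`` is the L2 norm of each cell's shift vector.
    """

    shifts: np.ndarray
    covariate: str
    gene_scores: np.ndarray
    cell_magnitudes: np.ndarray
    gene_ids: list
    cell_ids: list


def de_vector_field(
    model: DecompositionModel,
    covariate: str,
    cells: Optional[Sequence[int]] = None,
) -> VectorFieldResult:
    """Covariate-induced expression shifts D_t B[:, cells] and their summaries."""
    if model.D is None or model.covariate_names is None:
        raise ValueError(
            "model was fitted without a sample design; refit with covariates "
            "to compute differential-expression vector fields"
        )
    if covariate not in model.covariate_names:
        raise KeyError(
            f"covariate '{covariate}' not in design; available: {model.covariate_names}"
        )
    t = model.covariate_names.index(covariate)
    idx = np.arange(model.n_cells) if cells is None else np.asarray(cells, dtype=np.int64)
    Dt = model.D[t]
    shifts = Dt @ model.B[:, idx]
    n = max(shifts.shape[1], 1)
    gene_scores = np.sqrt((shifts ** 2).sum(axis=1) / n)
    cell_magnitudes = np.sqrt((shifts ** 2).sum(axis=0))
    return VectorFieldResult(
        shifts=shifts,
        covariate=covariate,
        gene_scores=gene_scores,
        cell_magnitudes=cell_magnitudes,
        gene_ids=list(model.gene_ids),
        cell_ids=[model.cell_ids[j] for j in idx],
    )


def program_activities(
    model: DecompositionModel, cells: Optional[Sequence[int]] = None
) -> np.ndarray:
    """Per-cell program / regulon activities W B[:, cells].

    W is kept consistent with the QR gauge at every iteration, so
    A (W b_n) is exactly the model's reference reconstruction Z b_n.
    """
    if model.W is None:
        raise ValueError(
            "model was fitted without a gene-program prior; refit with a "
            "prior (e.g. a GMT regulon file) to compute activities"
        )
    idx = np.arange(model.n_cells) if cells is None else np.asarray(cells, dtype=np.int64)
    return model.W @ model.B[:, idx]


def integrated_embedding(model: DecompositionModel) -> pd.DataFrame:
    """Cells x K latent coordinates (B^T) with cell ids, for neighborhood/UMAP tools."""
    cols = [f"factor_{k + 1}" for k in range(model.K)]
    return pd.DataFrame(model.B.T.copy(), index=pd.Index(model.cell_ids, name="cell_id"), columns=cols)
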