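"""Reference-based cell-type deconvolution at marker CpGs.

Each sample's betas at a small marker panel are modelled as a convex
combination of cell-type reference profiles: ``b = P w + e`` with ``w >= 0``
and ``sum(w) = 1``. Proportions are estimated by simplex-constrained least
squares; the headline readout is the leukocyte fraction, used to check that
cell-composition differences between tissues do not masquerade as outlier
methylation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .data_io import BetaMatrix, DataValidationError

logger = logging.getLogger("methylomp")


@dataclass
class CellTypeReference:
    """Marker x cell-type matrix of reference mean betas.

    Requires at least two cell types, at least as many markers as cell
    types, values in [0, 1], and a ``leukocyte`` column (the readout this
    analysis exists for).
    """

    profile: pd.DataFrame  # index: marker probe ids; columns: cell types

    def __post_init__(self) -> None:
        if self.profile.shape[1] < 2:
            raise DataValidationError("reference needs >= 2 cell types")
        if self.profile.shape[0] < self.profile.shape[1]:
            raise DataValidationError("reference needs at least as many markers as cell types")
        vals = self.profile.to_numpy(dtype=float)
        if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
            raise DataValidationError("reference betas must be finite and in [0, 1]")
        if "leukocyte" not in self.profile.columns:
            raise DataValidationError("reference must include a 'leukocyte' cell type")

    @property
    def marker_probe_ids(self) -> list[str]:
        return list(self.profile.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.profile.columns)


def read_celltype_reference(path: str | Path, delimiter: str | None = None) -> CellTypeReference:
    sep = "," if str(path).endswith(".csv") else "\t"
    if delimiter is not None:
        sep = delimiter
    return CellTypeReference(pd.read_csv(path, sep=sep, index_col=0))


def write_celltype_reference(ref: CellTypeReference, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    ref.profile.to_csv(path, sep=sep, index_label="probe_id")


def _simplex_lsq(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """argmin ||A w - b||^2 subject to w >= 0, sum(w) = 1."""
    k = A.shape[1]
    w0 = np.full(k, 1.0 / k)
    res = optimize.minimize(
        lambda w: float(np.sum((A @ w - b) ** 2)),
        w0,
        jac=lambda w: 2.0 * A.T @ (A @ w - b),
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: np.sum(w) - 1.0,
                      "jac": lambda w: np.ones_like(w)}],
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 500},
    )
    w = np.clip(res.x, 0.0, None)
    return w / w.sum()


def estimate_proportions(m: BetaMatrix, ref: CellTypeReference) -> pd.DataFrame:
    """Per-sample cell-type proportions (samples x cell types).

    Markers absent from the matrix are reported and dropped; at least as
    many markers as cell types must survive per sample (missing betas are
    dropped per sample). A rank-deficient reference at the surviving markers
    is an error, since proportions would be unidentifiable.
    """
    present = [p for p in ref.marker_probe_ids if p in set(m.probe_ids)]
    absent = [p for p in ref.marker_probe_ids if p not in set(m.probe_ids)]
    if absent:
        logger.warning("markers absent from matrix: %s", absent)
    k = len(ref.cell_types)
    if len(present) < k:
        raise DataValidationError(
            f"only {len(present)} markers present; need >= {k} (number of cell types)"
        )
    sub = m.df.loc[present]
    rows = []
    for sample in m.sample_ids:
        b = sub[sample].to_numpy(dtype=float)
        ok = ~np.isnan(b)
        if ok.sum() < k:
            raise DataValidationError(
                f"sample {sample!r}: only {int(ok.sum())} non-missing markers (need >= {k})"
            )
        A = ref.profile.loc[np.array(present)[ok]].to_numpy(dtype=float)
        if np.linalg.matrix_rank(A) < k:
            raise DataValidationError(
                f"reference is rank-deficient at the surviving markers for sample {sample!r}"
            )
        rows.append(_simplex_lsq(A, b[ok]))
    out = pd.DataFrame(rows, index=list(m.sample_ids), columns=ref.cell_types)
    out.index.name = "sample_id"
    return out
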