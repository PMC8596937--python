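"""Reference-based immune-cell deconvolution by constrained projection.

A whole-blood methylation profile is (to first order) a convex mixture of the
profiles of its constituent cell types, so the per-sample proportions of six
leukocyte subtypes (NK, TCD4, TCD8, Mono, Neu, B) are recovered by least
squares projection onto a signature matrix under nonnegativity and a
sum-to-one constraint. The constrained fit is solved as fully-constrained
least squares: nonnegative least squares on a system augmented with a heavily
weighted sum-to-one row, followed by exact renormalisation onto the simplex.

``mdnlr_ref`` converts the resulting proportions into the deconvolution-based
neutrophil-to-lymphocyte ratio used to validate the CpG-level mdNLR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .marker_panel import MarkerPanel, ReferenceMethylome

DECONV_CELL_TYPES = ("NK", "TCD4", "TCD8", "Mono", "Neu", "B")
LYMPHOID = ("NK", "TCD4", "TCD8", "B")

#: weight on the sum-to-one row of the augmented NNLS system
_SUM_WEIGHT = 1e4
_RANK_TOL = 1e-8


@dataclass
class DeconvolutionResult:
    """Per-sample simplex proportions plus root-mean-square residual."""

    proportions: pd.DataFrame  # samples x cell types, rows sum to one
    residual: pd.Series  # RMS of (observed - fitted) betas

    def __post_init__(self) -> None:
        w = self.proportions.to_numpy()
        if (w < -1e-12).any():
            raise ValueError("negative proportion in deconvolution result")
        if not np.allclose(w.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("proportions must sum to one")


def validate_signature(X: pd.DataFrame) -> None:
    vals = X.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("signature matrix contains missing values")
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("signature betas must lie in [0, 1]")
    rank = np.linalg.matrix_rank(vals, tol=_RANK_TOL)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank on the rest
        collinear = [
            c
            for i, c in enumerate(X.columns)
            if np.linalg.matrix_rank(np.delete(vals, i, axis=1), tol=_RANK_TOL)
            == np.linalg.matrix_rank(vals, tol=_RANK_TOL)
        ]
        raise ValueError(f"signature matrix is rank-deficient; collinear columns: {collinear}")


def signature_from_panel(
    ref: ReferenceMethylome,
    panel: MarkerPanel,
    cell_types=DECONV_CELL_TYPES,
    max_probes: int = 50,
) -> pd.DataFrame:
    """Signature matrix from panel markers: top probes by margin.

    Uses the ISUS of the deconvolved cell types plus the opposing mdNLR
    markers, restricted to the reference's columns for ``cell_types``.
    """
    specs = [s for t, ss in panel.isus.items() if t in cell_types for s in ss]
    specs += panel.neu_methylated + panel.panlym_methylated
    specs = sorted(specs, key=lambda s: (-(s.margin if s.margin == s.margin else 0.0), s.probe_id))
    probes = list(dict.fromkeys(s.probe_id for s in specs))[:max_probes]
    X = ref.betas.loc[probes, list(cell_types)]
    validate_signature(X)
    return X


def _solve_one(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float]:
    """Simplex-constrained least squares for one sample (complete data)."""
    n_probes, n_types = X.shape
    A = np.vstack([X, _SUM_WEIGHT * np.ones((1, n_types))])
    b = np.concatenate([y, [_SUM_WEIGHT]])
    w, _ = nnls(A, b)
    total = w.sum()
    if total <= 0:
        raise RuntimeError("degenerate NNLS solution (all-zero weights)")
    w = w / total
    resid = float(np.sqrt(np.mean((y - X @ w) ** 2)))
    return w, resid


def estimate_proportions(y: pd.Series, X: pd.DataFrame) -> tuple[pd.Series, float]:
    """Proportions for one sample: argmin ||y - Xw||^2 s.t. w >= 0, sum w = 1.

    Probes with a missing beta in ``y`` are dropped; at least as many usable
    probes as cell types are required.
    """
    validate_signature(X)
    y = y.reindex(X.index)
    keep = y.notna()
    if int(keep.sum()) < X.shape[1]:
        raise ValueError(
            f"only {int(keep.sum())} usable probes for {X.shape[1]} cell types"
        )
    w, resid = _solve_one(y[keep].to_numpy(dtype=float), X.loc[keep].to_numpy(dtype=float))
    return pd.Series(w, index=X.columns, name=y.name), resid


def deconvolve(betas: pd.DataFrame, X: pd.DataFrame) -> DeconvolutionResult:
    """Deconvolve every sample of a samples x probes beta matrix."""
    validate_signature(X)
    missing = [p for p in X.index if p not in betas.columns]
    if missing:
        raise KeyError(f"signature probes absent from beta matrix: {missing}")
    rows, resids = [], []
    sub = betas[X.index]
    for sample_id, y in sub.iterrows():
        w, r = estimate_proportions(y, X)
        rows.append(w)
        resids.append(r)
    props = pd.DataFrame(rows, index=sub.index)
    return DeconvolutionResult(props, pd.Series(resids, index=sub.index, name="residual"))


def mdnlr_ref(w, eps: float = 1e-6):
    """Deconvolution-based NLR: Neu proportion / (NK + TCD4 + TCD8 + B).

    Monocytes are excluded from the denominator. Accepts a single proportion
    Series or the samples x cell-types DataFrame.
    """
    if isinstance(w, pd.DataFrame):
        lym = w[list(LYMPHOID)].sum(axis=1).clip(lower=eps)
        return w["Neu"] / lym
    lym = max(float(sum(w[c] for c in LYMPHOID)), eps)
    return float(w["Neu"]) / lym
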