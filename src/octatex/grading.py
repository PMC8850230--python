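"""PCA textural grading of a cohort of autocorrelation curves.

Each subject's radial autocorrelation curve (lags d = 1..L; the d = 0 bin is
identically 1 and carries no information) is one row of a curve matrix.
Principal component analysis of that matrix concentrates nearly all of the
between-subject variance on the first component, and the PC1 score serves as
a one-dimensional textural grading index: low scores correspond to fine,
control-like textures, high scores to coarse, flow-void-dominated ones.
The PCA sign is intrinsically arbitrary, so the index is oriented so that
the control-group mean is the lower one (or, without labels, so that the
PC1 loadings sum to a non-negative value).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .texture import AutocorrCurve


@dataclass
class CurveMatrix:
    """Subjects x lag-bins matrix of rho values (d = 1..L)."""

    values: np.ndarray
    row_ids: list[str]
    groups: list[str]
    lags_px: np.ndarray
    layer: str = ""


@dataclass
class GradingResult:
    """PCA decomposition of a curve matrix.

    ``scores_pc1`` is the grading index; ``loadings`` has one row per
    component (per-lag weights); ``orientation`` records whether and why
    the PC1 sign was flipped.
    """

    scores_pc1: np.ndarray
    scores: np.ndarray
    explained_ratio: np.ndarray
    loadings: np.ndarray
    mean_curve: np.ndarray
    row_ids: list[str]
    groups: list[str]
    lags_px: np.ndarray
    orientation: str = "raw"


def stack_curves(curves: Sequence[AutocorrCurve]) -> CurveMatrix:
    """Assemble curves into a matrix, dropping the constant d = 0 column."""
    if len(curves) < 3:
        raise ValueError("need at least 3 curves for a cohort matrix")
    grid = curves[0].lags_px
    for c in curves[1:]:
        if not np.array_equal(c.lags_px, grid):
            raise ValueError("curves have mismatched lag grids")
    values = np.vstack([c.rho[1:] for c in curves])
    return CurveMatrix(
        values=values,
        row_ids=[c.subject_id for c in curves],
        groups=[c.group for c in curves],
        lags_px=grid[1:],
        layer=curves[0].layer,
    )


def fit_pca(m: CurveMatrix) -> GradingResult:
    """PCA on centred, unscaled columns (all columns share the rho unit).

    Components come from a full SVD; explained-variance ratios are the
    squared singular values normalised to sum to 1.
    """
    x = np.asarray(m.values, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    if np.allclose(x.var(axis=0), 0):
        raise ValueError("degenerate matrix: no column variance")
    pca = PCA(n_components=min(x.shape), svd_solver="full")
    scores = pca.fit_transform(x)
    return GradingResult(
        scores_pc1=scores[:, 0].copy(),
        scores=scores,
        explained_ratio=pca.explained_variance_ratio_,
        loadings=pca.components_,
        mean_curve=pca.mean_,
        row_ids=list(m.row_ids),
        groups=list(m.groups),
        lags_px=m.lags_px,
    )


def orient_index(g: GradingResult) -> GradingResult:
    """Fix the PC1 sign so controls sit at the low end of the index.

    If both group labels are present, flip when the control mean exceeds
    the case mean.  Without labels, flip when the PC1 loadings sum to a
    negative value (so a uniformly elevated curve scores high).
    """
    groups = np.asarray(g.groups)
    has_controls = (groups == "control").any()
    has_cases = (groups == "case").any()
    if has_controls and has_cases:
        flip = g.scores_pc1[groups == "control"].mean() > g.scores_pc1[
            groups == "case"
        ].mean()
        rule = "control-mean-low"
    else:
        flip = g.loadings[0].sum() < 0
        rule = "loading-sum-nonnegative"
    if not flip:
        return replace(g, orientation=rule)
    scores = g.scores.copy()
    scores[:, 0] *= -1
    loadings = g.loadings.copy()
    loadings[0] *= -1
    return replace(
        g,
        scores_pc1=-g.scores_pc1,
        scores=scores,
        loadings=loadings,
        orientation=f"{rule} (flipped)",
    )


def grade_cohort(curves: Sequence[AutocorrCurve]) -> GradingResult:
    """stack -> fit -> orient convenience path."""
    return orient_index(fit_pca(stack_curves(curves)))


def grading_to_frame(g: GradingResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": g.row_ids,
            "group": g.groups,
            "grading_index": g.scores_pc1,
            "pc1_explained_ratio": g.explained_ratio[0],
        }
    )


def loadings_to_frame(g: GradingResult) -> pd.DataFrame:
    df = pd.DataFrame(
        g.loadings.T,
        columns=[f"pc{i + 1}" for i in range(g.loadings.shape[0])],
    )
    df.insert(0, "lag_px", g.lags_px)
    return df
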