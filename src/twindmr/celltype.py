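"""Reference-based cell-type deconvolution and composition adjustment.

Whole-blood methylation is a mixture over leukocyte populations, and
disease-discordant co-twins can differ in composition; left uncorrected this
masquerades as differential methylation. Each sample's beta vector at a set
of discriminating probes is modelled as a convex combination of reference
cell-type profiles; the mixing weights are estimated by least squares
constrained to the probability simplex (non-negative, summing to one), and
composition effects are then removed per CpG by residualizing on the
estimated proportions.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from twindmr.core_io import BetaMatrix, ValidationError

logger = logging.getLogger(__name__)


class EstimationError(RuntimeError):
    """Deconvolution impossible (e.g. fewer usable probes than cell types)."""


@dataclasses.dataclass
class CellTypeReference:
    """Mean beta profile per cell type at a panel of discriminating probes."""

    probe_ids: list[str]
    cell_types: list[str]
    profiles: np.ndarray  # probes x cell types, in [0, 1]

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=float)
        if len(self.cell_types) < 2:
            raise ValidationError("reference needs at least 2 cell types")
        if self.profiles.shape != (len(self.probe_ids), len(self.cell_types)):
            raise ValidationError("reference profile shape mismatch")
        if len(self.probe_ids) < len(self.cell_types):
            raise ValidationError("reference needs at least as many probes as cell types")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.profiles, index=self.probe_ids, columns=self.cell_types)


# weight of the sum-to-one constraint row in the augmented NNLS system;
# large enough that the residual sum deviation is O(1e-8) before the final
# exact normalization
_SUM_PENALTY = 1e4


def _simplex_lstsq(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||A w - b||^2 s.t. w >= 0, sum w = 1, via penalty-augmented NNLS."""
    scale = max(np.abs(A).max(), 1.0)
    aug_A = np.vstack([A / scale, _SUM_PENALTY * np.ones((1, A.shape[1]))])
    aug_b = np.concatenate([b / scale, [_SUM_PENALTY]])
    w, _ = nnls(aug_A, aug_b)
    total = w.sum()
    if total <= 0:
        # degenerate sample; fall back to uniform weights
        return np.full(A.shape[1], 1.0 / A.shape[1])
    return w / total


def estimate_proportions(betas: BetaMatrix, ref: CellTypeReference) -> pd.DataFrame:
    """Estimate per-sample cell-type proportions on the probability simplex.

    Returns a samples x cell-types frame of weights; rows sum to one within
    1e-8. Reference probes absent from the beta matrix are dropped with a
    warning; a sample's missing entries are dropped for that sample only.
    """
    index = {p: i for i, p in enumerate(betas.probe_ids)}
    usable = [(j, index[p]) for j, p in enumerate(ref.probe_ids) if p in index]
    if len(usable) < len(ref.cell_types):
        raise EstimationError(
            f"only {len(usable)} reference probes usable for {len(ref.cell_types)} cell types"
        )
    if len(usable) < len(ref.probe_ids):
        logger.warning(
            "deconvolution: %d of %d reference probes absent from beta matrix",
            len(ref.probe_ids) - len(usable), len(ref.probe_ids),
        )
    ref_rows = np.array([j for j, _ in usable])
    beta_rows = np.array([i for _, i in usable])
    A_full = ref.profiles[ref_rows, :]
    B = betas.values[beta_rows, :]

    weights = np.empty((betas.n_samples, len(ref.cell_types)))
    for s in range(betas.n_samples):
        b = B[:, s]
        ok = ~np.isnan(b)
        if ok.sum() < len(ref.cell_types):
            raise EstimationError(
                f"sample {betas.sample_ids[s]!r}: fewer usable probes than cell types"
            )
        weights[s] = _simplex_lstsq(A_full[ok], b[ok])
    return pd.DataFrame(weights, index=betas.sample_ids, columns=ref.cell_types)


def adjust_for_celltype(betas: BetaMatrix, proportions: pd.DataFrame) -> BetaMatrix:
    """Remove composition effects: per CpG, residualize on the proportions.

    Each CpG's beta vector is regressed (OLS, intercept included, one
    proportion column dropped to break the sum-to-one collinearity) on the
    sample proportions; the adjusted value is residual + grand mean, clipped
    back to [0, 1]. With identical proportions everywhere the output equals
    the input.
    """
    missing = [s for s in betas.sample_ids if s not in proportions.index]
    if missing:
        raise ValidationError(f"no proportion estimate for samples: {missing[:5]}")
    W = proportions.loc[betas.sample_ids].to_numpy(dtype=float)
    # drop the last cell type, then any constant columns
    W = W[:, :-1]
    keep = W.std(axis=0) > 1e-12
    if not keep.all():
        logger.warning("adjustment: dropped %d constant proportion columns", int((~keep).sum()))
    W = W[:, keep]
    if W.shape[1] == 0:
        return BetaMatrix(list(betas.probe_ids), list(betas.sample_ids), betas.values.copy())

    Y = betas.values
    adjusted = np.full_like(Y, np.nan)
    X_full = np.column_stack([np.ones(len(W)), W])

    nan_mask = np.isnan(Y)
    complete = ~nan_mask.any(axis=1)
    if complete.any():
        adjusted[complete] = _residual_plus_mean(X_full, Y[complete].T).T
    # group remaining probes by missingness pattern so each pattern is one solve
    rest = np.flatnonzero(~complete)
    if rest.size:
        patterns: dict[bytes, list[int]] = {}
        for i in rest:
            patterns.setdefault(nan_mask[i].tobytes(), []).append(i)
        for key, rows in patterns.items():
            ok = ~np.frombuffer(key, dtype=bool)
            if ok.sum() <= X_full.shape[1]:
                adjusted[np.ix_(rows, ok)] = Y[np.ix_(rows, ok)]  # too few samples to adjust
                continue
            adjusted[np.ix_(rows, ok)] = _residual_plus_mean(X_full[ok], Y[np.ix_(rows, ok)].T).T
    return BetaMatrix(list(betas.probe_ids), list(betas.sample_ids), np.clip(adjusted, 0.0, 1.0))


def _residual_plus_mean(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residuals of each column of Y on X, recentred at that column's mean."""
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    return resid + Y.mean(axis=0, keepdims=True)
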