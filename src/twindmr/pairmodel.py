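"""Per-CpG co-twin regression and differentially methylated position calling.

For disease-discordant monozygotic pairs the response at each CpG is the
within-pair beta difference delta = beta(case) - beta(control); genetic and
shared-environment effects cancel in the difference. Delta is regressed by
ordinary least squares on pair-level covariates (smoking, anti-CCP antibody,
DMARD treatment, age, sex). The exposures enter as raw 0/1 indicators and
the matching covariates (age, sex) are mean-centered, so the intercept
alpha estimates the disease effect on methylation in unexposed pairs of
average age and sex (alpha > 0: hypermethylation in the affected twin) and each slope
estimates exposure-linked differential methylation on top of it (slope > 0:
exposure-associated hypermethylation) — an exposure-driven signal therefore
loads on its slope surface, not on alpha. Two-sided t tests against zero
give per-CpG p-values;
genome-wide calling uses Benjamini-Hochberg FDR < 0.05 with an uncorrected
suggestive threshold of 5e-5.

OLS coefficients are linear functionals of the per-probe delta vector, so the
module also exposes a :class:`SurfaceProjector` that evaluates a chosen
coefficient surface for arbitrary sign-flips of the pair deltas with a few
matrix products — the work-horse of permutation inference in :mod:`twindmr.dmr`.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from twindmr.core_io import BetaMatrix, DesignError, PairDesign
from twindmr.qc import BETA_EPS

logger = logging.getLogger(__name__)

COVARIATES = ("smoking", "accp", "dmard", "age", "sex")
EXPOSURES = ("smoking", "accp", "dmard")


@dataclasses.dataclass
class PairDifferences:
    """Per-probe, per-pair responses: delta = case - control and clipped ratio."""

    probe_ids: list[str]
    pair_ids: list[str]
    delta: np.ndarray  # probes x pairs, NaN where either twin is missing
    ratio: np.ndarray  # probes x pairs, case/control after clipping

    @property
    def n_pairs_per_probe(self) -> np.ndarray:
        return (~np.isnan(self.delta)).sum(axis=1)

    def response(self, kind: str = "delta") -> np.ndarray:
        if kind == "delta":
            return self.delta
        if kind == "logratio":
            return np.log(self.ratio)
        raise ValueError(f"unknown response {kind!r}")


def compute_pair_differences(betas: BetaMatrix, design: PairDesign) -> PairDifferences:
    """Case-minus-control delta and case/control ratio per probe per pair.

    A pair with a missing value at a probe is omitted at that probe (NaN).
    Ratios use values clipped into [BETA_EPS, 1 - BETA_EPS].
    """
    design.validate_against(betas)
    case_idx = [betas.sample_index(s) for s in design.table["case_sample"]]
    ctrl_idx = [betas.sample_index(s) for s in design.table["control_sample"]]
    case = betas.values[:, case_idx]
    ctrl = betas.values[:, ctrl_idx]
    delta = case - ctrl
    case_c = np.clip(case, BETA_EPS, 1 - BETA_EPS)
    ctrl_c = np.clip(ctrl, BETA_EPS, 1 - BETA_EPS)
    ratio = case_c / ctrl_c
    return PairDifferences(
        probe_ids=list(betas.probe_ids),
        pair_ids=design.pair_ids,
        delta=delta,
        ratio=ratio,
    )


def _usable_pairs(design: PairDesign, covariates: Sequence[str]) -> np.ndarray:
    """Boolean mask of pairs with complete covariates (missing smoking excluded)."""
    mask = np.ones(design.n_pairs, dtype=bool)
    for cov in covariates:
        mask &= ~design.table[cov].isna().to_numpy()
    return mask


def _independent_columns(X: np.ndarray, tol: float = 1e-10) -> list[int]:
    """Greedy maximal set of linearly independent columns, keeping column 0."""
    keep = [0]
    basis = X[:, [0]]
    for j in range(1, X.shape[1]):
        col = X[:, j]
        coef, *_ = np.linalg.lstsq(basis, col, rcond=None)
        resid = col - basis @ coef
        if np.linalg.norm(resid) > tol * max(1.0, np.linalg.norm(col)):
            keep.append(j)
            basis = np.column_stack([basis, col])
    return keep


def _design_matrix(Csub: np.ndarray, names: Sequence[str]) -> np.ndarray:
    """Intercept plus covariates: exposures raw 0/1, everything else centered.

    Keeping the exposures uncentered makes the intercept the disease effect
    in unexposed pairs, so exposure-driven signal loads on its slope surface
    and not on alpha; centering the matching covariates (age, sex) keeps the
    intercept referenced to an average pair rather than to age zero.
    """
    n = Csub.shape[0]
    cols = [np.ones(n)]
    for j, name in enumerate(names):
        col = Csub[:, j]
        if name not in EXPOSURES:
            col = col - col.mean()
        cols.append(col)
    return np.column_stack(cols)


def _pattern_groups(nan_mask: np.ndarray) -> dict[bytes, np.ndarray]:
    """Group probe rows by identical missingness pattern across pairs."""
    complete = ~nan_mask.any(axis=1)
    groups: dict[bytes, list[int]] = {}
    if complete.any():
        groups[np.zeros(nan_mask.shape[1], dtype=bool).tobytes()] = list(np.flatnonzero(complete))
    for i in np.flatnonzero(~complete):
        groups.setdefault(nan_mask[i].tobytes(), []).append(i)
    return {k: np.asarray(v, dtype=int) for k, v in groups.items()}


def fit_cpg_models(
    diffs: PairDifferences,
    design: PairDesign,
    covariates: Sequence[str] = COVARIATES,
    min_pairs: int = 10,
    response: str = "delta",
) -> pd.DataFrame:
    """Fit the per-CpG paired model for every probe.

    Returns a frame indexed by probe_id with columns ``alpha``, ``alpha_se``,
    ``alpha_p``, per-covariate ``<cov>_slope`` / ``<cov>_se`` / ``<cov>_p``,
    and ``n_pairs_used``. Probes with fewer than ``min_pairs`` complete pairs
    are reported with NaN statistics. Rank-deficient covariate columns are
    dropped per missingness pattern with a log message.
    """
    covariates = list(covariates)
    unknown = set(covariates) - set(design.table.columns)
    if unknown:
        raise DesignError(f"covariates absent from design: {sorted(unknown)}")
    usable = _usable_pairs(design, covariates)
    Y = diffs.response(response)[:, usable]
    C = design.table.loc[usable, covariates].to_numpy(dtype=float) if covariates else np.empty((int(usable.sum()), 0))

    n_probes = len(diffs.probe_ids)
    cols = ["alpha", "alpha_se", "alpha_p"]
    for cov in covariates:
        cols += [f"{cov}_slope", f"{cov}_se", f"{cov}_p"]
    out = pd.DataFrame(np.nan, index=pd.Index(diffs.probe_ids, name="probe_id"), columns=cols)
    out["n_pairs_used"] = 0

    for key, rows in _pattern_groups(np.isnan(Y)).items():
        ok = ~np.frombuffer(key, dtype=bool)
        n = int(ok.sum())
        out.iloc[rows, out.columns.get_loc("n_pairs_used")] = n
        if n < min_pairs:
            continue
        Csub = C[ok]
        Xfull = _design_matrix(Csub, covariates)
        keep = _independent_columns(Xfull)
        if len(keep) < Xfull.shape[1]:
            dropped = [(["(intercept)"] + covariates)[j] for j in range(Xfull.shape[1]) if j not in keep]
            logger.info("rank-deficient design for %d probes: dropped %s", len(rows), dropped)
        X = Xfull[:, keep]
        p = X.shape[1]
        df = n - p
        XtX_inv = np.linalg.inv(X.T @ X)
        Ysub = np.nan_to_num(Y[rows][:, ok])
        coefs = Ysub @ X @ XtX_inv  # probes x p
        resid = Ysub - coefs @ X.T
        rss = (resid**2).sum(axis=1)
        if df > 0:
            sigma2 = rss / df
            se = np.sqrt(np.outer(sigma2, np.diag(XtX_inv)))
            with np.errstate(divide="ignore", invalid="ignore"):
                tval = coefs / se
            pval = 2 * stats.t.sf(np.abs(tval), df)
        else:
            se = np.full_like(coefs, np.nan)
            pval = np.full_like(coefs, np.nan)
        names = ["alpha"] + covariates
        for out_j, full_j in enumerate(keep):
            name = names[full_j]
            prefix = "alpha" if name == "alpha" else name
            suffix = ("", "_se", "_p") if name == "alpha" else ("_slope", "_se", "_p")
            out.iloc[rows, out.columns.get_loc(prefix + suffix[0])] = coefs[:, out_j]
            out.iloc[rows, out.columns.get_loc(prefix + suffix[1])] = se[:, out_j]
            out.iloc[rows, out.columns.get_loc(prefix + suffix[2])] = pval[:, out_j]
    return out


def fold_changes(betas: BetaMatrix, design: PairDesign) -> pd.Series:
    """Per-probe fold change: mean case beta / mean control beta (clipped).

    Values below one reflect relative hypomethylation in the affected twin,
    above one relative hypermethylation.
    """
    design.validate_against(betas)
    case_idx = [betas.sample_index(s) for s in design.table["case_sample"]]
    ctrl_idx = [betas.sample_index(s) for s in design.table["control_sample"]]
    vals = np.clip(betas.values, BETA_EPS, 1 - BETA_EPS)
    with np.errstate(invalid="ignore"):
        fc = np.nanmean(vals[:, case_idx], axis=1) / np.nanmean(vals[:, ctrl_idx], axis=1)
    return pd.Series(fc, index=pd.Index(betas.probe_ids, name="probe_id"), name="fold_change")


def call_dmps(
    stats_table: pd.DataFrame,
    fdr_threshold: float = 0.05,
    suggestive_p: float = 5e-5,
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    """Benjamini-Hochberg FDR and suggestive calling over the fitted table.

    Adds ``fdr`` / ``significant`` / ``suggestive`` for the disease intercept
    and ``<cov>_fdr`` for each requested covariate slope. Probes without a
    fitted p-value are left NaN and excluded from the correction.
    """
    out = stats_table.copy()
    out["fdr"] = _bh(out["alpha_p"])
    out["significant"] = out["fdr"] < fdr_threshold
    out["suggestive"] = out["alpha_p"] < suggestive_p
    for cov in covariates:
        out[f"{cov}_fdr"] = _bh(out[f"{cov}_p"])
    return out


def _bh(p: pd.Series) -> pd.Series:
    adj = pd.Series(np.nan, index=p.index)
    ok = p.notna()
    if ok.any():
        adj.loc[ok] = multipletests(p[ok].to_numpy(), method="fdr_bh")[1]
    return adj


@dataclasses.dataclass
class SurfaceProjector:
    """Evaluates one coefficient surface under per-pair sign flips.

    The OLS coefficient for a probe is ``w . delta`` where ``w`` depends only
    on the (fixed) design matrix and the probe's missingness pattern. Flipping
    a pair's case/control labels negates its delta while the covariates stay
    attached to the pair, so a permuted surface is ``D (w * s)`` per pattern
    block — identical algebra to refitting every probe.
    """

    n_probes: int
    n_pairs: int
    fittable: np.ndarray  # bool per probe: enough complete pairs to fit
    _blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]]
    # each block: (probe rows, pair columns (global ids), weight vector, delta sub-block)

    def surface(self, signs: np.ndarray | None = None) -> np.ndarray:
        """Coefficient per probe; NaN where unfittable. signs: +-1 per pair."""
        out = np.full(self.n_probes, np.nan)
        for rows, cols, w, D in self._blocks:
            ws = w if signs is None else w * signs[cols]
            out[rows] = D @ ws
        return out


def build_projector(
    diffs: PairDifferences,
    design: PairDesign,
    coefficient: str = "alpha",
    covariates: Sequence[str] = COVARIATES,
    min_pairs: int = 10,
    response: str = "delta",
) -> SurfaceProjector:
    """Precompute the linear maps delta -> coefficient for every probe.

    ``coefficient`` is ``"alpha"`` (disease intercept) or a covariate name;
    the weight row is the corresponding row of ``(X'X)^{-1} X'`` for that
    probe's missingness pattern. Probes whose pattern leaves fewer than
    ``min_pairs`` pairs, or whose requested coefficient was dropped for rank
    deficiency, are marked unfittable.
    """
    covariates = list(covariates)
    if coefficient != "alpha" and coefficient not in covariates:
        raise DesignError(f"coefficient {coefficient!r} not among covariates {covariates}")
    usable = _usable_pairs(design, covariates)
    usable_ids = np.flatnonzero(usable)
    Y = diffs.response(response)[:, usable]
    C = design.table.loc[usable, covariates].to_numpy(dtype=float) if covariates else np.empty((int(usable.sum()), 0))

    n_probes = len(diffs.probe_ids)
    fittable = np.zeros(n_probes, dtype=bool)
    blocks = []
    names = ["alpha"] + covariates
    target = names.index(coefficient if coefficient != "alpha" else "alpha")
    for key, rows in _pattern_groups(np.isnan(Y)).items():
        ok = ~np.frombuffer(key, dtype=bool)
        n = int(ok.sum())
        if n < min_pairs:
            continue
        Csub = C[ok]
        Xfull = _design_matrix(Csub, covariates)
        keep = _independent_columns(Xfull)
        if target not in keep:
            continue
        X = Xfull[:, keep]
        W = np.linalg.inv(X.T @ X) @ X.T  # p x n
        w = W[keep.index(target)]
        cols = usable_ids[ok]
        D = np.ascontiguousarray(np.nan_to_num(Y[rows][:, ok]))
        blocks.append((rows, cols, w, D))
        fittable[rows] = True
    return SurfaceProjector(
        n_probes=n_probes,
        n_pairs=design.n_pairs,
        fittable=fittable,
        _blocks=blocks,
    )
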