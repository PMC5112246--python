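"""Bump hunting: regional DMR detection with permutation inference.

Per-CpG regression coefficients (disease intercept or an exposure slope) are
smoothed within clusters of nearby probes, thresholded at the 99th percentile
of the genome-wide smoothed values, and maximal runs of probes beyond a
threshold become candidate regions ("bumps"). Each bump is scored by its
area — the sum of absolute smoothed coefficients over its probes — and
ranked by area. Significance comes from permuting case-control status within
pairs: each permutation flips the sign of a pair's delta (covariates stay
attached to the pair), the fit/smooth/detect chain is re-run with the
observed thresholds held fixed, and the null areas yield

* ``fwer_p`` — fraction of per-permutation maximum areas strictly larger
  than the observed area (family-wise error rate);
* ``suggestive`` — observed area exceeds the smallest per-permutation
  maximum area;
* ``emp_p`` — fraction of all null bumps strictly larger (uncorrected);
* ``fdr`` — ratio of the expected null count at or above the observed area
  to the observed count, monotonized.

Smoothing is a fixed linear operator (local linear with tricube weights for
clusters of at least ``min_probes_loess`` probes, a window-3 running mean
for smaller clusters, identity for clusters of one or two probes), so
permuted surfaces are smoothed by a single sparse matrix product.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from twindmr.core_io import BetaMatrix, GenomicRegion, PairDesign, ProbeManifest, ValidationError
from twindmr.pairmodel import (
    COVARIATES,
    PairDifferences,
    build_projector,
    compute_pair_differences,
    fold_changes,
)

logger = logging.getLogger(__name__)

SURFACES = ("alpha", "smoking", "accp", "dmard")

BUMP_COLUMNS = ["chrom", "start", "end", "n_probes", "direction", "area", "peak", "start_idx", "end_idx", "rank"]


def cluster_probes(manifest: ProbeManifest | pd.DataFrame, maxgap: int = 500) -> pd.DataFrame:
    """Assign maximal probe clusters: consecutive probes on a chromosome with
    inter-probe gaps <= maxgap share a cluster (inclusive boundary)."""
    table = manifest.table if isinstance(manifest, ProbeManifest) else manifest
    out = table.reset_index(drop=True).copy()
    if len(out) == 0:
        out["cluster"] = pd.Series(dtype=int)
        return out
    pos = out["pos"].to_numpy()
    chrom = out["chrom"].to_numpy()
    new_cluster = np.ones(len(out), dtype=bool)
    same_chrom = chrom[1:] == chrom[:-1]
    gaps = np.diff(pos)
    new_cluster[1:] = ~(same_chrom & (gaps <= maxgap))
    out["cluster"] = np.cumsum(new_cluster) - 1
    return out


def build_smoother(
    pos: np.ndarray,
    cluster_ids: np.ndarray,
    bandwidth: int = 1000,
    min_probes_loess: int = 7,
) -> sparse.csr_matrix:
    """Linear smoothing operator over probes, block-structured by cluster.

    Reproduces constants exactly and, for the local-linear branch, linear
    trends at every probe whose window has full rank.
    """
    n = len(pos)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for _, idx in _cluster_slices(cluster_ids):
        p = pos[idx].astype(float)
        k = len(idx)
        if k <= 2:
            for i in range(k):
                rows.append(idx[i]); cols.append(idx[i]); vals.append(1.0)
        elif k < min_probes_loess:
            for i in range(k):
                lo, hi = max(0, i - 1), min(k, i + 2)
                w = 1.0 / (hi - lo)
                for j in range(lo, hi):
                    rows.append(idx[i]); cols.append(idx[j]); vals.append(w)
        else:
            for i in range(k):
                d = p - p[i]
                u = np.abs(d) / float(bandwidth)
                w = np.where(u < 1.0, (1.0 - u**3) ** 3, 0.0)
                w[i] = max(w[i], 1.0)  # own probe always contributes
                active = w > 0
                wa, da = w[active], d[active]
                s0, s1, s2 = wa.sum(), (wa * da).sum(), (wa * da * da).sum()
                denom = s0 * s2 - s1 * s1
                if denom > 1e-12 * max(s0 * s2, 1.0):
                    li = wa * (s2 - da * s1) / denom  # local linear evaluated at probe i
                else:
                    li = wa / s0  # degenerate window: weighted mean
                for j, v in zip(idx[active], li):
                    rows.append(idx[i]); cols.append(j); vals.append(float(v))
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def _cluster_slices(cluster_ids: np.ndarray):
    """Yield (cluster_id, member index array); members are contiguous."""
    if len(cluster_ids) == 0:
        return
    boundaries = np.flatnonzero(np.diff(cluster_ids) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(cluster_ids)]])
    for s, e in zip(starts, ends):
        yield cluster_ids[s], np.arange(s, e)


def compute_thresholds(
    smoothed: np.ndarray, quantile_level: float = 0.99, symmetric: bool = True
) -> tuple[float, float]:
    """Upper and lower bump thresholds from the genome-wide smoothed surface.

    Symmetric mode (default): +-(``quantile_level`` quantile of |smoothed|).
    Signed mode: the ``quantile_level`` and ``1 - quantile_level`` quantiles
    of the signed values. Linear-interpolation quantiles.
    """
    vals = np.asarray(smoothed, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValidationError("no smoothed values to compute thresholds from")
    if np.ptp(vals) == 0:
        logger.warning("degenerate thresholds: all smoothed values identical (%g)", vals[0])
    if symmetric:
        q = float(np.quantile(np.abs(vals), quantile_level))
        return q, -q
    return (
        float(np.quantile(vals, quantile_level)),
        float(np.quantile(vals, 1.0 - quantile_level)),
    )


def _runs(mask: np.ndarray, cluster_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start/end (inclusive) index pairs of maximal True runs within clusters."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    brk = np.flatnonzero((np.diff(idx) != 1) | (cluster_ids[idx[1:]] != cluster_ids[idx[:-1]]))
    starts = idx[np.concatenate([[0], brk + 1])]
    ends = idx[np.concatenate([brk, [idx.size - 1]])]
    return starts, ends


def _run_areas_peaks(smoothed, starts, ends):
    a = np.abs(smoothed)
    csum = np.concatenate([[0.0], np.cumsum(a)])
    areas = csum[ends + 1] - csum[starts]
    peaks = np.array([a[s : e + 1].max() for s, e in zip(starts, ends)]) if len(starts) else np.empty(0)
    return areas, peaks


def detect_bumps(
    smoothed: np.ndarray,
    probe_table: pd.DataFrame,
    thresholds: tuple[float, float],
) -> pd.DataFrame:
    """Maximal runs of smoothed values beyond a threshold, ranked by area.

    ``probe_table`` carries chrom/pos/cluster aligned to ``smoothed``. Hyper
    and hypo runs are detected separately and never merged; ties in area are
    broken by (chrom, start).
    """
    upper, lower = thresholds
    cluster_ids = probe_table["cluster"].to_numpy()
    pos = probe_table["pos"].to_numpy()
    chrom = probe_table["chrom"].to_numpy()
    s = np.where(np.isnan(smoothed), 0.0, smoothed)
    records = []
    for direction, mask in (("hyper", s > upper), ("hypo", s < lower)):
        starts, ends = _runs(mask, cluster_ids)
        areas, peaks = _run_areas_peaks(s, starts, ends)
        for st, en, area, peak in zip(starts, ends, areas, peaks):
            records.append(
                {
                    "chrom": chrom[st],
                    "start": int(pos[st]),
                    "end": int(pos[en]),
                    "n_probes": int(en - st + 1),
                    "direction": direction,
                    "area": float(area),
                    "peak": float(peak),
                    "start_idx": int(st),
                    "end_idx": int(en),
                }
            )
    bumps = pd.DataFrame(records, columns=BUMP_COLUMNS[:-1])
    if len(bumps):
        bumps = bumps.sort_values(
            ["area", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
        ).reset_index(drop=True)
    bumps["rank"] = np.arange(1, len(bumps) + 1)
    return bumps


def _null_areas(smoothed: np.ndarray, cluster_ids: np.ndarray, upper: float, lower: float) -> np.ndarray:
    """All bump areas (both directions) for one permuted surface."""
    s = np.where(np.isnan(smoothed), 0.0, smoothed)
    out = []
    for mask in (s > upper, s < lower):
        starts, ends = _runs(mask, cluster_ids)
        if starts.size:
            areas, _ = _run_areas_peaks(s, starts, ends)
            out.append(areas)
    return np.concatenate(out) if out else np.empty(0)


def _sign_matrix(n_pairs: int, n_perm: int, seed, exhaustive: bool) -> np.ndarray:
    if exhaustive:
        if n_pairs > 16:
            raise ValidationError("exhaustive enumeration limited to 16 pairs")
        return np.array(list(itertools.product((1.0, -1.0), repeat=n_pairs)))
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.choice([1.0, -1.0], size=(n_perm, n_pairs))


@dataclasses.dataclass
class DMRConfig:
    """Knobs of the regional analysis (defaults follow the study's settings
    where it states them; smoothing choices are this package's)."""

    maxgap: int = 500
    bandwidth: int = 1000
    min_probes_loess: int = 7
    quantile_level: float = 0.99
    symmetric_thresholds: bool = True
    n_perm: int = 1000
    min_pairs: int = 10
    response: str = "delta"
    covariates: tuple[str, ...] = COVARIATES


def permutation_inference(
    betas: BetaMatrix,
    design: PairDesign,
    manifest: ProbeManifest,
    coefficient: str = "alpha",
    config: DMRConfig | None = None,
    seed: int | None = 0,
    exhaustive: bool = False,
    diffs: PairDifferences | None = None,
    probe_fold_change: pd.Series | None = None,
) -> pd.DataFrame:
    """Full regional analysis for one coefficient surface.

    Runs fit -> smooth -> threshold -> detect on the observed data, then
    re-runs the chain under ``config.n_perm`` random within-pair label swaps
    (or, with ``exhaustive=True``, all 2^n sign assignments) with thresholds
    fixed at the observed ones, and attaches ``fwer_p``, ``suggestive``,
    ``emp_p`` and ``fdr`` to every observed bump. Strict ">" in all tail
    counts; boundary zeros are flagged (``fwer_boundary`` means
    fwer_p < 1/n_perm) rather than corrected.
    """
    config = config or DMRConfig()
    covariates = list(config.covariates)
    table = manifest.aligned_to(betas.probe_ids)
    if len(table) == 0:
        raise ValidationError("no manifest probes present in beta matrix")
    sub = betas.select_probes(table["probe_id"].tolist())
    if diffs is None:
        diffs = compute_pair_differences(sub, design)
    projector = build_projector(
        diffs, design, coefficient, covariates, config.min_pairs, config.response
    )
    if not projector.fittable.any():
        raise ValidationError(f"no fittable probes for surface {coefficient!r}")
    keep = projector.fittable
    table = table.loc[keep].reset_index(drop=True)
    observed_surface = projector.surface()[keep]

    probe_table = cluster_probes(table, config.maxgap)
    cluster_ids = probe_table["cluster"].to_numpy()
    smoother = build_smoother(
        probe_table["pos"].to_numpy(), cluster_ids, config.bandwidth, config.min_probes_loess
    )
    smoothed = smoother @ observed_surface
    thresholds = compute_thresholds(smoothed, config.quantile_level, config.symmetric_thresholds)
    bumps = detect_bumps(smoothed, probe_table, thresholds)

    signs = _sign_matrix(design.n_pairs, config.n_perm, seed, exhaustive)
    n_perm = signs.shape[0]
    max_areas = np.zeros(n_perm)
    obs_areas = bumps["area"].to_numpy() if len(bumps) else np.empty(0)
    null_count_ge = np.zeros(len(obs_areas))
    null_count_gt = np.zeros(len(obs_areas))
    n_null_total = 0
    for k in range(n_perm):
        surf = projector.surface(signs[k])[keep]
        areas = _null_areas(smoother @ surf, cluster_ids, *thresholds)
        max_areas[k] = areas.max() if areas.size else 0.0
        if areas.size and obs_areas.size:
            sorted_areas = np.sort(areas)
            null_count_ge += areas.size - np.searchsorted(sorted_areas, obs_areas, side="left")
            null_count_gt += areas.size - np.searchsorted(sorted_areas, obs_areas, side="right")
        n_null_total += areas.size

    out = bumps.copy()
    if len(out):
        out["fwer_p"] = [(max_areas > a).mean() for a in obs_areas]
        out["fwer_boundary"] = out["fwer_p"] == 0.0
        out["suggestive"] = obs_areas > max_areas.min()
        if n_null_total > 0:
            out["emp_p"] = null_count_gt / n_null_total
            out["emp_p_boundary"] = out["emp_p"] == 0.0
        else:
            out["emp_p"] = 0.0
            out["emp_p_boundary"] = True
        out["fdr"] = _area_fdr(obs_areas, null_count_ge, n_perm)
        if probe_fold_change is not None:
            fc = probe_fold_change.reindex(probe_table["probe_id"]).to_numpy()
            out["fold_change"] = [
                float(np.nanmean(fc[s : e + 1]))
                for s, e in zip(out["start_idx"], out["end_idx"])
            ]
    else:
        for col in ("fwer_p", "emp_p", "fdr"):
            out[col] = pd.Series(dtype=float)
        for col in ("fwer_boundary", "suggestive", "emp_p_boundary"):
            out[col] = pd.Series(dtype=bool)
    out.attrs["n_perm"] = n_perm
    out.attrs["n_null_bumps"] = n_null_total
    out.attrs["thresholds"] = thresholds
    return out


def _area_fdr(obs_areas: np.ndarray, null_count_ge: np.ndarray, n_perm: int) -> np.ndarray:
    """Ratio-of-expected-counts FDR, monotonized by reverse cumulative min.

    obs_areas must be sorted descending (detect_bumps guarantees it); the
    observed count at area a_i is then simply i+1.
    """
    if obs_areas.size == 0:
        return np.empty(0)
    expected = null_count_ge / n_perm
    observed = np.arange(1, obs_areas.size + 1, dtype=float)
    raw = np.minimum(1.0, expected / observed)
    return np.minimum.accumulate(raw[::-1])[::-1]


def covariate_dmrs(
    betas: BetaMatrix,
    design: PairDesign,
    manifest: ProbeManifest,
    surfaces: Sequence[str] = SURFACES,
    config: DMRConfig | None = None,
    seed: int | None = 0,
    exhaustive: bool = False,
) -> dict[str, pd.DataFrame]:
    """Run the regional analysis for the disease intercept and each exposure.

    Surfaces whose covariate is constant across usable pairs are skipped with
    a warning. Each table carries per-bump fold change (mean per-probe
    case/control ratio over the bump's probes).
    """
    config = config or DMRConfig()
    fc = fold_changes(betas, design)
    results: dict[str, pd.DataFrame] = {}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(len(surfaces))
    for surface, child in zip(surfaces, child_seeds):
        if surface != "alpha":
            vals = design.table[surface].dropna()
            if vals.nunique() < 2:
                logger.warning("surface %r skipped: covariate constant across pairs", surface)
                continue
        results[surface] = permutation_inference(
            betas,
            design,
            manifest,
            coefficient=surface,
            config=config,
            seed=child,
            exhaustive=exhaustive,
            probe_fold_change=fc,
        )
    return results


def bumps_to_regions(bumps: pd.DataFrame) -> list[GenomicRegion]:
    return [
        GenomicRegion(chrom=row.chrom, start=int(row.start), end=int(row.end), n_probes=int(row.n_probes))
        for row in bumps.itertuples()
    ]
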