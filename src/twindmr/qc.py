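"""Beta-value computation and probe-level quality control.

Beta values follow the Illumina convention beta = M / (M + U + 100), where M
and U are methylated and unmethylated signal intensities and the +100 offset
regularizes low-intensity probes. Measurements whose detection p-value
exceeds a threshold (default 0.01, strict) are treated as missing, and
probes with more than a fixed fraction of missing entries (default 5%,
strict) are dropped.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from twindmr.core_io import BetaMatrix, ValidationError

logger = logging.getLogger(__name__)

#: clip bound applied before any ratio computation downstream
BETA_EPS = 1e-6


@dataclasses.dataclass
class IntensityPair:
    """Methylated (M) and unmethylated (U) signal intensities, elementwise >= 0."""

    probe_ids: list[str]
    sample_ids: list[str]
    M: np.ndarray
    U: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        if self.M.shape != self.U.shape:
            raise ValidationError(f"M shape {self.M.shape} != U shape {self.U.shape}")
        for name, arr in (("M", self.M), ("U", self.U)):
            if np.nanmin(arr) < 0 if arr.size else False:
                raise ValidationError(f"negative {name} intensity")


def compute_beta(intensities: IntensityPair, offset: float = 100.0) -> BetaMatrix:
    """beta = M / (M + U + offset); lies in [0, 1) for finite intensities."""
    values = intensities.M / (intensities.M + intensities.U + offset)
    return BetaMatrix(
        probe_ids=list(intensities.probe_ids),
        sample_ids=list(intensities.sample_ids),
        values=values,
    )


def mask_by_detection(betas: BetaMatrix, detp: np.ndarray, threshold: float = 0.01) -> BetaMatrix:
    """Set entries whose detection p-value is strictly above ``threshold`` missing."""
    detp = np.asarray(detp, dtype=float)
    if detp.shape != betas.values.shape:
        raise ValidationError(
            f"detection-p shape {detp.shape} does not match beta matrix {betas.values.shape}"
        )
    values = betas.values.copy()
    failed = detp > threshold
    values[failed] = np.nan
    n = int(failed.sum())
    if n:
        logger.info("detection-p masking: %d measurements set missing (threshold %g)", n, threshold)
    return BetaMatrix(list(betas.probe_ids), list(betas.sample_ids), values)


def filter_high_missing(
    betas: BetaMatrix, max_missing_frac: float = 0.05
) -> tuple[BetaMatrix, list[str]]:
    """Drop probes whose missing fraction is strictly above ``max_missing_frac``.

    Returns the filtered matrix and the list of dropped probe ids.
    """
    frac = np.isnan(betas.values).mean(axis=1)
    drop = frac > max_missing_frac
    dropped = [p for p, d in zip(betas.probe_ids, drop) if d]
    if dropped:
        logger.info("missingness filter: dropped %d of %d probes", len(dropped), betas.n_probes)
    return betas.select_probes(~drop), dropped


def clip_betas(betas: BetaMatrix, eps: float = BETA_EPS) -> BetaMatrix:
    """Clip non-missing values into [eps, 1-eps] ahead of ratio computations."""
    values = betas.values.copy()
    with np.errstate(invalid="ignore"):
        n_clipped = int(((values < eps) | (values > 1 - eps)).sum())
    values = np.clip(values, eps, 1 - eps)
    if n_clipped:
        logger.info("clipped %d beta values into [%g, %g]", n_clipped, eps, 1 - eps)
    return BetaMatrix(list(betas.probe_ids), list(betas.sample_ids), values)
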