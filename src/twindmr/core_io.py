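"""Domain types and tabular/BED readers and writers shared by all stages.

Coordinates are 1-based inclusive everywhere inside the package; the BED
writer alone emits the standard 0-based half-open convention. Missing values
in tabular files are encoded by a single configurable token (default "NA").
All joins between tables are by identifier, never by position in the file.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file violates the expected tabular layout (duplicates, bad codes)."""


class ValidationError(ValueError):
    """Well-formed input carries values that violate a domain invariant."""


class DesignError(ValueError):
    """The pair design sheet is internally inconsistent."""


NA_TOKEN = "NA"


@dataclasses.dataclass
class BetaMatrix:
    """CpG-by-sample matrix of methylation fractions with missingness.

    ``values`` is a float array with NaN marking missing entries; every
    non-missing entry lies in [0, 1]. Row order follows ``probe_ids`` and
    column order follows ``sample_ids``.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("beta matrix must be 2-dimensional")
        n_p, n_s = self.values.shape
        if n_p != len(self.probe_ids) or n_s != len(self.sample_ids):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            raise FormatError("duplicate probe ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            bad = np.argwhere(~np.isnan(self.values) & ((self.values < 0) | (self.values > 1)))
            p, s = bad[0]
            raise ValidationError(
                f"beta value out of [0,1] at probe {self.probe_ids[p]}, "
                f"sample {self.sample_ids[s]}: {self.values[p, s]}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(
            probe_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise DesignError(f"sample id {sample_id!r} not present in beta matrix") from None

    def select_probes(self, keep: Sequence[str] | np.ndarray) -> "BetaMatrix":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {p: i for i, p in enumerate(self.probe_ids)}
            idx = np.array([pos[p] for p in keep], dtype=int)
        return BetaMatrix(
            probe_ids=[self.probe_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=self.values[idx, :],
        )


@dataclasses.dataclass
class ProbeManifest:
    """Genomic locations of probes: probe_id, chrom, 1-based pos, optional gene.

    Rows are sorted by (chrom, pos) on construction; probe ids are unique.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"probe_id", "chrom", "pos"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"manifest missing columns: {sorted(missing)}")
        if "gene" not in self.table.columns:
            self.table = self.table.assign(gene="")
        if self.table["probe_id"].duplicated().any():
            dup = self.table.loc[self.table["probe_id"].duplicated(), "probe_id"].iloc[0]
            raise FormatError(f"duplicate probe id in manifest: {dup}")
        self.table = (
            self.table.assign(pos=self.table["pos"].astype(np.int64))
            .sort_values(["chrom", "pos"], kind="mergesort")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> list[str]:
        return self.table["probe_id"].tolist()

    def aligned_to(self, probe_ids: Sequence[str]) -> pd.DataFrame:
        """Manifest rows for the given probes, kept in manifest (chrom,pos) order."""
        sub = self.table[self.table["probe_id"].isin(set(probe_ids))]
        return sub.reset_index(drop=True)


_BINARY = {0, 1}


@dataclasses.dataclass
class PairDesign:
    """Disease-discordant pair structure with pair-level covariates.

    One row per pair: ``pair_id``, ``case_sample`` (affected twin),
    ``control_sample`` (unaffected co-twin), binary exposures ``smoking``
    (may be NaN = unknown), ``accp`` (anti-CCP antibody positivity),
    ``dmard`` (current DMARD treatment), plus ``age`` and ``sex``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"pair_id", "case_sample", "control_sample", "smoking", "accp", "dmard", "age", "sex"}
        missing = required - set(t.columns)
        if missing:
            raise FormatError(f"pair design missing columns: {sorted(missing)}")
        if t["pair_id"].duplicated().any():
            raise DesignError("duplicate pair ids")
        same = t["case_sample"] == t["control_sample"]
        if same.any():
            raise DesignError(f"pair {t.loc[same, 'pair_id'].iloc[0]} lists the same sample twice")
        all_samples = pd.concat([t["case_sample"], t["control_sample"]])
        if all_samples.duplicated().any():
            dup = all_samples[all_samples.duplicated()].iloc[0]
            raise DesignError(f"sample {dup!r} appears in more than one pair slot")
        for col in ("accp", "dmard", "sex"):
            vals = set(pd.unique(t[col].dropna()))
            if not vals <= _BINARY:
                raise FormatError(f"non-binary code in column {col!r}: {sorted(vals - _BINARY)}")
            if t[col].isna().any():
                raise FormatError(f"column {col!r} may not be missing")
        smoking_vals = set(pd.unique(t["smoking"].dropna()))
        if not smoking_vals <= _BINARY:
            raise FormatError(f"non-binary smoking code: {sorted(smoking_vals - _BINARY)}")
        self.table = t.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def pair_ids(self) -> list[str]:
        return self.table["pair_id"].astype(str).tolist()

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    def smoking_missing(self) -> pd.Series:
        return self.table["smoking"].isna()

    def validate_against(self, betas: BetaMatrix) -> None:
        known = set(betas.sample_ids)
        for col in ("case_sample", "control_sample"):
            unknown = set(self.table[col]) - known
            if unknown:
                raise DesignError(f"{col} ids absent from beta matrix: {sorted(unknown)[:5]}")


@dataclasses.dataclass(frozen=True)
class GenomicRegion:
    """A contiguous genomic interval, 1-based inclusive on both ends."""

    chrom: str
    start: int
    end: int
    n_probes: int = 1

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValidationError(f"region end {self.end} < start {self.start}")
        if self.n_probes < 1:
            raise ValidationError("region must contain at least one probe")


def _read_table(path, na_token: str) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        na_values=[na_token],
        keep_default_na=False,
        dtype={0: str},
        float_precision="round_trip",
    )


def read_beta_matrix(path, na_token: str = NA_TOKEN) -> BetaMatrix:
    """Read a tab-delimited beta matrix: first column probe ids, header samples."""
    frame = _read_table(path, na_token)
    if frame.shape[1] < 2:
        raise FormatError("beta matrix needs a probe-id column plus at least one sample")
    frame = frame.set_index(frame.columns[0])
    if len(frame) == 0:
        raise FormatError("no probes in beta matrix")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in beta matrix: {exc}") from None
    return BetaMatrix(
        probe_ids=[str(i) for i in frame.index],
        sample_ids=[str(c) for c in frame.columns],
        values=values,
    )


def write_beta_matrix(betas: BetaMatrix, path, na_token: str = NA_TOKEN) -> None:
    frame = betas.to_frame()
    frame.index.name = "probe_id"
    frame.to_csv(path, sep="\t", na_rep=na_token, float_format="%.17g")


def read_manifest(path, na_token: str = NA_TOKEN) -> ProbeManifest:
    return ProbeManifest(_read_table(path, na_token))


def read_pair_design(path, na_token: str = NA_TOKEN) -> PairDesign:
    """Read the pair design sheet; missing smoking stays missing, never imputed."""
    t = _read_table(path, na_token)
    return PairDesign(t)


def write_pair_design(design: PairDesign, path, na_token: str = NA_TOKEN) -> None:
    design.table.to_csv(path, sep="\t", index=False, na_rep=na_token)


def write_bed(regions: Iterable[GenomicRegion], scores: Sequence[float], path, names: Sequence[str] | None = None) -> None:
    """Write regions as BED (0-based half-open), score in column 5."""
    regions = list(regions)
    if names is None:
        names = [f"region_{i + 1}" for i in range(len(regions))]
    if not (len(regions) == len(scores) == len(names)):
        raise ValidationError("regions, scores and names must have equal length")
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tname\tscore\n")
        for region, score, name in zip(regions, scores, names):
            fh.write(f"{region.chrom}\t{region.start - 1}\t{region.end}\t{name}\t{score:g}\n")


def read_bed(path) -> pd.DataFrame:
    """Read a BED file back to 1-based inclusive coordinates.

    Returns a frame with columns chrom, start, end, name, score (name/score
    optional in the input).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"BED line with fewer than 3 columns: {line!r}")
            chrom, start0, end = parts[0], int(parts[1]), int(parts[2])
            if end < start0:
                raise FormatError(f"BED end < start: {line!r}")
            rows.append(
                {
                    "chrom": chrom,
                    "start": start0 + 1,
                    "end": end,
                    "name": parts[3] if len(parts) > 3 else "",
                    "score": float(parts[4]) if len(parts) > 4 else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])
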