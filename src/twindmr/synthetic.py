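"""Synthetic paired methylation datasets with known ground truth.

The generator emulates the statistical structure the co-twin analysis
assumes: 28 disease-discordant monozygotic pairs; probes arranged in
clusters along chromosomes; a bimodal beta-value baseline (most CpGs are
either mostly unmethylated or mostly methylated); within-pair correlation
exceeding between-pair correlation (a shared pair-level latent value plus
independent twin-level noise); binary exposures at the study cohort's
prevalences (ever-smoking 0.69 with 0.14 missing, anti-CCP 0.61, DMARD
0.68); optional cell-type mixture structure; optional detection failures;
and spiked differentially methylated regions tied to the disease intercept
or to a single exposure, recorded in a ground-truth table for recovery
tests. Effects are additive on the beta-difference scale, added to the
affected twin (all pairs for disease spikes, exposed pairs only for
covariate spikes), with final values clipped to [0, 1].
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from twindmr.celltype import CellTypeReference
from twindmr.core_io import BetaMatrix, PairDesign, ProbeManifest, ValidationError


@dataclasses.dataclass(frozen=True)
class SpikeSpec:
    """One ground-truth differentially methylated region to inject.

    ``colocate=True`` places this spike on the same probes as the previous
    one — used to model a region driven in opposite directions by two
    different exposures.
    """

    surface: str = "alpha"  # "alpha" or a covariate name
    effect: float = 0.15  # per-probe effect on the delta scale, signed
    n_probes: int = 10
    colocate: bool = False


@dataclasses.dataclass
class CellTypeSpec:
    """Mixture structure: per-sample simplex weights over reference profiles.

    ``case_shift`` moves the affected twin's expected weight toward the first
    cell type, creating a composition-driven (not methylation-driven) pair
    difference at the reference-distinguishing probes.
    """

    n_probes: int = 120
    n_cell_types: int = 6
    base_proportions: tuple[float, ...] = (0.35, 0.20, 0.15, 0.12, 0.10, 0.08)
    concentration: float = 60.0
    case_shift: float = 0.0


@dataclasses.dataclass
class SyntheticTruth:
    """Everything the generator knows that the pipeline must recover."""

    regions: pd.DataFrame  # chrom, start, end, n_probes, surface, effect, first_idx, last_idx
    seed: int
    noise_sd: float
    pair_sd: float
    reference: CellTypeReference | None = None
    proportions: pd.DataFrame | None = None  # true per-sample weights


def generate_manifest(
    n_chrom: int = 1,
    n_clusters: int = 500,
    probes_per_cluster: tuple[int, int] = (6, 14),
    gap_within: tuple[int, int] = (30, 400),
    gap_between: tuple[int, int] = (2000, 10000),
    seed: int = 0,
) -> ProbeManifest:
    """Sorted probe manifest with known cluster structure.

    Within-cluster gaps are drawn from ``gap_within`` (keep its upper end at
    or below the analysis maxgap so clusters are recoverable) and
    between-cluster gaps from ``gap_between`` (keep its lower end above
    maxgap). The generating cluster id is recorded in a ``true_cluster``
    column.
    """
    if n_clusters < 1 or n_chrom < 1:
        raise ValidationError("need at least one chromosome and one cluster")
    rng = np.random.default_rng(seed)
    rows = []
    probe_no = 0
    clusters_per_chrom = np.full(n_chrom, n_clusters // n_chrom)
    clusters_per_chrom[: n_clusters % n_chrom] += 1
    cluster_id = 0
    for c in range(n_chrom):
        chrom = f"chr{c + 1}"
        pos = 10_000
        for _ in range(int(clusters_per_chrom[c])):
            k = int(rng.integers(probes_per_cluster[0], probes_per_cluster[1] + 1))
            for j in range(k):
                if j > 0:
                    pos += int(rng.integers(gap_within[0], gap_within[1] + 1))
                rows.append({"probe_id": f"cg{probe_no:07d}", "chrom": chrom, "pos": pos, "true_cluster": cluster_id})
                probe_no += 1
            pos += int(rng.integers(gap_between[0], gap_between[1] + 1))
            cluster_id += 1
    return ProbeManifest(pd.DataFrame(rows))


def generate_pairs(
    n_pairs: int = 28,
    smoking_prev: float = 0.69,
    accp_prev: float = 0.61,
    dmard_prev: float = 0.68,
    missing_smoking: float = 0.14,
    female_frac: float = 0.78,
    age_mean: float = 56.0,
    age_sd: float = 10.0,
    seed: int = 0,
) -> PairDesign:
    """Pair design sheet at the study cohort's exposure prevalences.

    Exposures are Bernoulli draws; smoking status is set missing at the
    stated rate; ages are normal (truncated to [30, 80]); sex is shared by
    both twins of a pair (1 = female).
    """
    rng = np.random.default_rng(seed)
    smoking = rng.random(n_pairs) < smoking_prev
    smoking = smoking.astype(float)
    smoking[rng.random(n_pairs) < missing_smoking] = np.nan
    table = pd.DataFrame(
        {
            "pair_id": [f"pair{i + 1:02d}" for i in range(n_pairs)],
            "case_sample": [f"pair{i + 1:02d}_case" for i in range(n_pairs)],
            "control_sample": [f"pair{i + 1:02d}_ctrl" for i in range(n_pairs)],
            "smoking": smoking,
            "accp": (rng.random(n_pairs) < accp_prev).astype(int),
            "dmard": (rng.random(n_pairs) < dmard_prev).astype(int),
            "age": np.clip(rng.normal(age_mean, age_sd, n_pairs), 30, 80).round(1),
            "sex": (rng.random(n_pairs) < female_frac).astype(int),
        }
    )
    return PairDesign(table)


def make_reference(probe_ids: list[str], n_cell_types: int = 6, seed: int = 0) -> CellTypeReference:
    """Synthetic discriminating reference panel: independent per-probe,
    per-cell-type methylation levels drawn from a U-shaped distribution."""
    rng = np.random.default_rng(seed)
    profiles = rng.beta(0.5, 0.5, size=(len(probe_ids), n_cell_types))
    profiles = 0.05 + 0.9 * profiles  # keep strictly inside (0, 1)
    return CellTypeReference(
        probe_ids=list(probe_ids),
        cell_types=[f"ct{i + 1}" for i in range(n_cell_types)],
        profiles=profiles,
    )


def _place_spikes(manifest: ProbeManifest, spikes, excluded: set[int], rng) -> pd.DataFrame:
    """Pick disjoint clusters large enough for each spike, record regions."""
    table = manifest.table
    if "true_cluster" not in table.columns:
        raise ValidationError("manifest lacks true_cluster structure; use generate_manifest")
    sizes = table.groupby("true_cluster").size()
    regions = []
    used = set(excluded)
    prev_span: tuple[int, int] | None = None
    for spike in spikes:
        if spike.colocate:
            if prev_span is None:
                raise ValidationError("colocate spike needs a preceding spike")
            first, last = prev_span
            if last - first + 1 != spike.n_probes:
                raise ValidationError("colocated spikes must cover the same number of probes")
        else:
            candidates = sizes[(sizes >= spike.n_probes) & ~sizes.index.isin(used)].index.to_numpy()
            if candidates.size == 0:
                raise ValidationError(f"no free cluster with >= {spike.n_probes} probes for spike {spike}")
            cluster = int(candidates[rng.integers(len(candidates))])
            used.add(cluster)
            members = np.flatnonzero((table["true_cluster"] == cluster).to_numpy())
            first = members[0]
            last = members[spike.n_probes - 1]
        prev_span = (first, last)
        regions.append(
            {
                "chrom": table["chrom"].iloc[first],
                "start": int(table["pos"].iloc[first]),
                "end": int(table["pos"].iloc[last]),
                "n_probes": spike.n_probes,
                "surface": spike.surface,
                "effect": spike.effect,
                "first_idx": int(first),
                "last_idx": int(last),
            }
        )
    return pd.DataFrame(
        regions,
        columns=["chrom", "start", "end", "n_probes", "surface", "effect", "first_idx", "last_idx"],
    )


def generate_dataset(
    manifest: ProbeManifest,
    design: PairDesign,
    spikes: list[SpikeSpec] | None = None,
    pair_sd: float = 0.10,
    noise_sd: float = 0.05,
    celltype: CellTypeSpec | None = None,
    detp_rate: float = 0.0,
    seed: int = 0,
) -> tuple[BetaMatrix, np.ndarray | None, SyntheticTruth]:
    """Generate a paired beta matrix (case and control columns per pair).

    Per probe: a bimodal baseline level, a shared pair-level deviation
    (sd ``pair_sd``), independent twin-level noise (sd ``noise_sd``), spiked
    effects added to the affected twin, optional cell-type mixture values at
    the reference probes, clipping to [0, 1]. Returns the beta matrix, a
    detection-p matrix (None when ``detp_rate`` is 0) and the ground truth.
    """
    rng = np.random.default_rng(seed)
    n_probes = len(manifest)
    n_pairs = design.n_pairs
    spikes = spikes or []

    # bimodal baseline: unmethylated mode near 0.1, methylated mode near 0.9
    high = rng.random(n_probes) < 0.5
    baseline = np.where(high, rng.beta(45, 5, n_probes), rng.beta(5, 45, n_probes))

    pair_latent = baseline[:, None] + rng.normal(0.0, pair_sd, size=(n_probes, n_pairs))
    case = pair_latent + rng.normal(0.0, noise_sd, size=(n_probes, n_pairs))
    ctrl = pair_latent + rng.normal(0.0, noise_sd, size=(n_probes, n_pairs))

    # cell-type mixture values overwrite the reference-panel probes
    reference = None
    true_props = None
    panel_clusters: set[int] = set()
    if celltype is not None:
        sizes = manifest.table.groupby("true_cluster").size()
        cum = sizes.cumsum()
        n_panel_clusters = int(np.searchsorted(cum.to_numpy(), celltype.n_probes) + 1)
        panel_clusters = set(sizes.index[:n_panel_clusters])
        panel_idx = np.flatnonzero(manifest.table["true_cluster"].isin(panel_clusters).to_numpy())
        reference = make_reference(
            [manifest.probe_ids[i] for i in panel_idx], celltype.n_cell_types, seed=seed + 1
        )
        base = np.asarray(celltype.base_proportions, dtype=float)
        base = base / base.sum()
        shifted = base.copy()
        shifted[0] += celltype.case_shift
        shifted = shifted / shifted.sum()
        w_case = rng.dirichlet(shifted * celltype.concentration, size=n_pairs)
        w_ctrl = rng.dirichlet(base * celltype.concentration, size=n_pairs)
        case[panel_idx, :] = reference.profiles @ w_case.T + rng.normal(0, noise_sd, (len(panel_idx), n_pairs))
        ctrl[panel_idx, :] = reference.profiles @ w_ctrl.T + rng.normal(0, noise_sd, (len(panel_idx), n_pairs))
        props = {}
        for i, row in design.table.iterrows():
            props[row["case_sample"]] = w_case[i]
            props[row["control_sample"]] = w_ctrl[i]
        true_props = pd.DataFrame.from_dict(props, orient="index", columns=reference.cell_types)

    regions = _place_spikes(manifest, spikes, panel_clusters, rng)
    exposures = {c: design.table[c].to_numpy(dtype=float) for c in ("smoking", "accp", "dmard")}
    # spiked regions get intermediate baselines (published twin DMRs sit at
    # intermediate methylation); at the bimodal extremes the [0,1] clipping
    # would silently compress the injected effect
    respiked: set[int] = set()
    for region in regions.itertuples():
        rows_idx = [i for i in range(region.first_idx, region.last_idx + 1) if i not in respiked]
        if rows_idx:
            shift = rng.beta(10, 10, len(rows_idx)) - baseline[rows_idx]
            case[rows_idx, :] += shift[:, None]
            ctrl[rows_idx, :] += shift[:, None]
            baseline[rows_idx] += shift
            respiked.update(rows_idx)
    for region in regions.itertuples():
        rows = slice(region.first_idx, region.last_idx + 1)
        if region.surface == "alpha":
            case[rows, :] += region.effect
        else:
            exposed = exposures[region.surface] == 1.0  # missing or unexposed pairs untouched
            case[rows, exposed] += region.effect

    sample_ids = []
    columns = []
    for i in range(n_pairs):
        sample_ids.extend([design.table["case_sample"].iloc[i], design.table["control_sample"].iloc[i]])
        columns.extend([case[:, i], ctrl[:, i]])
    values = np.clip(np.column_stack(columns), 0.0, 1.0)

    detp = None
    if detp_rate > 0:
        detp = rng.uniform(0.0, 0.005, size=values.shape)
        failed = rng.random(values.shape) < detp_rate
        detp[failed] = rng.uniform(0.02, 1.0, size=int(failed.sum()))

    betas = BetaMatrix(list(manifest.probe_ids), sample_ids, values)
    truth = SyntheticTruth(
        regions=regions,
        seed=seed,
        noise_sd=noise_sd,
        pair_sd=pair_sd,
        reference=reference,
        proportions=true_props,
    )
    return betas, detp, truth
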