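"""End-to-end orchestration and the command-line interface.

``run`` sequences QC -> cell-type adjustment -> per-CpG pair model -> DMP
table -> per-surface DMR tables -> BED export -> optional gene annotation,
writing every table, a config snapshot, the log and the seed into a run
directory. Outputs are pure functions of (inputs, config, seed); each table
carries the config hash in a leading comment line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from twindmr import annotate as annotate_mod
from twindmr import celltype as celltype_mod
from twindmr import core_io, qc, synthetic
from twindmr import dmr as dmr_mod
from twindmr import pairmodel
from twindmr.core_io import ValidationError

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The run configuration is invalid; raised before any compute."""


@dataclasses.dataclass
class PipelineConfig:
    """All knobs of a pipeline run; see docs/methods.md for rationale."""

    beta_matrix: str = ""
    manifest: str = ""
    pair_design: str = ""
    detection_p: str | None = None
    celltype_reference: str | None = None
    genes_bed: str | None = None
    out_dir: str = "run"
    na_token: str = "NA"
    seed: int = 1
    n_perm: int = 1000
    maxgap: int = 500
    bandwidth: int = 1000
    min_probes_loess: int = 7
    quantile_level: float = 0.99
    symmetric_thresholds: bool = True
    detp_threshold: float = 0.01
    max_missing_frac: float = 0.05
    min_pairs: int = 10
    response: str = "delta"
    covariates: tuple[str, ...] = pairmodel.COVARIATES
    surfaces: tuple[str, ...] = dmr_mod.SURFACES
    skip_celltype: bool = False
    celltype_mode: str = "residualize"  # or "covariate"
    fdr_threshold: float = 0.05
    suggestive_p: float = 5e-5

    def validate(self) -> None:
        if self.n_perm < 1:
            raise ConfigError("n_perm must be >= 1")
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        if self.response not in ("delta", "logratio"):
            raise ConfigError(f"unknown response {self.response!r}")
        if self.celltype_mode not in ("residualize", "covariate"):
            raise ConfigError(f"unknown celltype_mode {self.celltype_mode!r}")
        for name in ("beta_matrix", "manifest", "pair_design"):
            path = getattr(self, name)
            if not path:
                raise ConfigError(f"missing required input path: {name}")
            if not Path(path).exists():
                raise ConfigError(f"{name} path does not exist: {path}")
        for name in ("detection_p", "celltype_reference", "genes_bed"):
            path = getattr(self, name)
            if path and not Path(path).exists():
                raise ConfigError(f"{name} path does not exist: {path}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = list(self.covariates)
        d["surfaces"] = list(self.surfaces)
        return d

    def hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir")  # where results land does not change what they are
        payload = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("covariates", "surfaces"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _write_table(frame: pd.DataFrame, path: Path, config_hash: str, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, sep="\t", index=index, na_rep="NA")


def run(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("twindmr")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump({"config_hash": chash, **config.to_dict()}, fh, sort_keys=True)
        stage = "load"
        try:
            betas = core_io.read_beta_matrix(config.beta_matrix, config.na_token)
            manifest = core_io.read_manifest(config.manifest, config.na_token)
            design = core_io.read_pair_design(config.pair_design, config.na_token)
            design.validate_against(betas)
            logger.info("loaded %d probes x %d samples, %d pairs", betas.n_probes, betas.n_samples, design.n_pairs)

            stage = "qc"
            n_in = betas.n_probes
            if config.detection_p:
                detp = core_io.read_beta_matrix(config.detection_p, config.na_token)
                betas = qc.mask_by_detection(betas, detp.values, config.detp_threshold)
            betas, dropped = qc.filter_high_missing(betas, config.max_missing_frac)
            logger.info("qc: %d probes in, %d dropped, %d out", n_in, len(dropped), betas.n_probes)
            pd.Series(dropped, name="probe_id").to_csv(out / "dropped_probes.tsv", sep="\t", index=False)

            stage = "celltype"
            covariates = list(config.covariates)
            if config.celltype_reference and not config.skip_celltype:
                ref_frame = pd.read_csv(config.celltype_reference, sep="\t", index_col=0)
                ref = celltype_mod.CellTypeReference(
                    probe_ids=[str(i) for i in ref_frame.index],
                    cell_types=[str(c) for c in ref_frame.columns],
                    profiles=ref_frame.to_numpy(dtype=float),
                )
                props = celltype_mod.estimate_proportions(betas, ref)
                _write_table(props, out / "celltype_proportions.tsv", chash, index=True)
                if config.celltype_mode == "residualize":
                    betas = celltype_mod.adjust_for_celltype(betas, props)
                else:
                    diffs_w = (
                        props.loc[design.table["case_sample"]].to_numpy()
                        - props.loc[design.table["control_sample"]].to_numpy()
                    )
                    for j, ct in enumerate(props.columns[:-1]):
                        col = f"ctdiff_{ct}"
                        design.table[col] = diffs_w[:, j]
                        covariates.append(col)

            stage = "dmp"
            diffs = pairmodel.compute_pair_differences(betas, design)
            stats_table = pairmodel.fit_cpg_models(
                diffs, design, covariates, config.min_pairs, config.response
            )
            dmp_table = pairmodel.call_dmps(
                stats_table, config.fdr_threshold, config.suggestive_p,
                [c for c in covariates if c in pairmodel.EXPOSURES],
            )
            dmp_table = dmp_table.join(pairmodel.fold_changes(betas, design))
            loc = manifest.table.set_index("probe_id")[["chrom", "pos"]]
            dmp_table = loc.join(dmp_table, how="right")
            _write_table(dmp_table, out / "dmp_table.tsv", chash, index=True)
            logger.info(
                "dmp: %d significant (fdr<%g), %d suggestive (p<%g)",
                int(dmp_table["significant"].sum()), config.fdr_threshold,
                int(dmp_table["suggestive"].sum()), config.suggestive_p,
            )

            stage = "dmr"
            dmr_config = dmr_mod.DMRConfig(
                maxgap=config.maxgap,
                bandwidth=config.bandwidth,
                min_probes_loess=config.min_probes_loess,
                quantile_level=config.quantile_level,
                symmetric_thresholds=config.symmetric_thresholds,
                n_perm=config.n_perm,
                min_pairs=config.min_pairs,
                response=config.response,
                covariates=tuple(covariates),
            )
            surfaces = [s for s in config.surfaces if s == "alpha" or s in covariates]
            tables = dmr_mod.covariate_dmrs(
                betas, design, manifest, surfaces, dmr_config, seed=config.seed
            )
            genes = core_io.read_bed(config.genes_bed) if config.genes_bed else None
            for surface, table in tables.items():
                logger.info("dmr[%s]: %d putative regions", surface, len(table))
                export = table.drop(columns=["start_idx", "end_idx"])
                stage = "annotate"
                if genes is not None and len(table):
                    ann = annotate_mod.nearest_gene(dmr_mod.bumps_to_regions(table), genes)
                    export = export.assign(gene=ann["gene"].to_numpy(), gene_distance=ann["distance"].to_numpy())
                stage = "dmr"
                _write_table(export, out / f"dmr_{surface}.tsv", chash)
                core_io.write_bed(
                    dmr_mod.bumps_to_regions(table),
                    scores=table["area"].tolist(),
                    names=[f"{surface}_dmr_{r}" for r in table["rank"]],
                    path=out / f"dmr_{surface}.bed",
                )
        except Exception as exc:
            logger.error("stage %r failed: %s", stage, exc)
            raise
        logger.info("run complete: %s (config hash %s, seed %d)", out, chash, config.seed)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


# ---------------------------------------------------------------------------
# CLI: thin wrappers over the library


@click.group()
def cli() -> None:
    """Co-twin EWAS pipeline: paired regression and DMR bump hunting."""


@cli.command()
@click.option("--out-dir", type=click.Path(), required=True)
@click.option("--seed", type=int, required=True)
@click.option("--n-pairs", type=int, default=28, show_default=True)
@click.option("--n-clusters", type=int, default=500, show_default=True)
@click.option("--n-chrom", type=int, default=1, show_default=True)
@click.option("--pair-sd", type=float, default=0.10, show_default=True)
@click.option("--noise-sd", type=float, default=0.05, show_default=True)
@click.option("--detp-rate", type=float, default=0.002, show_default=True)
@click.option("--spike", "spikes", multiple=True,
              help="surface:effect:n_probes, e.g. alpha:0.15:10; repeatable")
@click.option("--celltype/--no-celltype", default=False, show_default=True,
              help="inject cell-type mixture structure and write a reference panel")
def simulate(out_dir, seed, n_pairs, n_clusters, n_chrom, pair_sd, noise_sd, detp_rate, spikes, celltype):
    """Generate a synthetic paired dataset with ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = synthetic.generate_manifest(n_chrom=n_chrom, n_clusters=n_clusters, seed=seed)
    design = synthetic.generate_pairs(n_pairs=n_pairs, seed=seed + 1)
    spike_specs = []
    for spec in spikes:
        surface, effect, n_probes = spec.split(":")
        spike_specs.append(synthetic.SpikeSpec(surface=surface, effect=float(effect), n_probes=int(n_probes)))
    ct = synthetic.CellTypeSpec(case_shift=0.05) if celltype else None
    betas, detp, truth = synthetic.generate_dataset(
        manifest, design, spike_specs, pair_sd=pair_sd, noise_sd=noise_sd,
        celltype=ct, detp_rate=detp_rate, seed=seed + 2,
    )
    core_io.write_beta_matrix(betas, out / "beta.tsv")
    manifest.table.to_csv(out / "manifest.tsv", sep="\t", index=False)
    core_io.write_pair_design(design, out / "design.tsv")
    if detp is not None:
        core_io.write_beta_matrix(
            core_io.BetaMatrix(betas.probe_ids, betas.sample_ids, np.clip(detp, 0, 1)),
            out / "detp.tsv",
        )
    truth.regions.to_csv(out / "truth_regions.tsv", sep="\t", index=False)
    if truth.reference is not None:
        truth.reference.to_frame().to_csv(out / "celltype_reference.tsv", sep="\t")
    click.echo(f"wrote synthetic dataset ({betas.n_probes} probes, {n_pairs} pairs) to {out}")


def _config_from_options(config_path, **overrides) -> PipelineConfig:
    config = PipelineConfig.from_yaml(config_path) if config_path else PipelineConfig()
    for key, value in overrides.items():
        if value is not None:
            setattr(config, key, value)
    return config


@cli.command(name="run")
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--beta-matrix", type=click.Path(), default=None)
@click.option("--manifest", type=click.Path(), default=None)
@click.option("--pair-design", type=click.Path(), default=None)
@click.option("--detection-p", type=click.Path(), default=None)
@click.option("--celltype-reference", type=click.Path(), default=None)
@click.option("--genes-bed", type=click.Path(), default=None)
@click.option("--out-dir", type=click.Path(), default=None)
@click.option("--seed", type=int, default=None)
@click.option("--n-perm", type=int, default=None)
@click.option("--maxgap", type=int, default=None)
@click.option("--bandwidth", type=int, default=None)
@click.option("--quantile", "quantile_level", type=float, default=None)
@click.option("--surfaces", type=str, default=None, help="comma-separated, e.g. alpha,smoking")
@click.option("--skip-celltype", is_flag=True, default=None)
def run_command(config_path, surfaces, **overrides):
    """Run the full pipeline from a config file and/or CLI overrides."""
    if surfaces is not None:
        overrides["surfaces"] = tuple(s.strip() for s in surfaces.split(","))
    try:
        config = _config_from_options(config_path, **overrides)
        out = run(config)
    except (ConfigError, ValidationError) as exc:
        raise click.ClickException(str(exc))
    click.echo(f"run complete: {out}")


@cli.command(name="qc")
@click.option("--beta-matrix", type=click.Path(exists=True), required=True)
@click.option("--detection-p", type=click.Path(exists=True), default=None)
@click.option("--out", type=click.Path(), required=True)
@click.option("--detp-threshold", type=float, default=0.01, show_default=True)
@click.option("--max-missing-frac", type=float, default=0.05, show_default=True)
def qc_command(beta_matrix, detection_p, out, detp_threshold, max_missing_frac):
    """Detection-p masking and probe missingness filtering."""
    betas = core_io.read_beta_matrix(beta_matrix)
    if detection_p:
        detp = core_io.read_beta_matrix(detection_p)
        betas = qc.mask_by_detection(betas, detp.values, detp_threshold)
    betas, dropped = qc.filter_high_missing(betas, max_missing_frac)
    core_io.write_beta_matrix(betas, out)
    click.echo(f"kept {betas.n_probes} probes, dropped {len(dropped)}")


@cli.command(name="celltype")
@click.option("--beta-matrix", type=click.Path(exists=True), required=True)
@click.option("--reference", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--proportions-out", type=click.Path(), default=None)
def celltype_command(beta_matrix, reference, out, proportions_out):
    """Estimate cell-type proportions and residualize them out."""
    betas = core_io.read_beta_matrix(beta_matrix)
    ref_frame = pd.read_csv(reference, sep="\t", index_col=0)
    ref = celltype_mod.CellTypeReference(
        probe_ids=[str(i) for i in ref_frame.index],
        cell_types=[str(c) for c in ref_frame.columns],
        profiles=ref_frame.to_numpy(dtype=float),
    )
    props = celltype_mod.estimate_proportions(betas, ref)
    if proportions_out:
        props.to_csv(proportions_out, sep="\t")
    adjusted = celltype_mod.adjust_for_celltype(betas, props)
    core_io.write_beta_matrix(adjusted, out)
    click.echo(f"adjusted {betas.n_probes} probes for {len(props.columns)} cell types")


@cli.command(name="dmp")
@click.option("--beta-matrix", type=click.Path(exists=True), required=True)
@click.option("--manifest", "manifest_path", type=click.Path(exists=True), required=True)
@click.option("--pair-design", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--min-pairs", type=int, default=10, show_default=True)
def dmp_command(beta_matrix, manifest_path, pair_design, out, min_pairs):
    """Per-CpG paired regression and DMP calling."""
    betas = core_io.read_beta_matrix(beta_matrix)
    manifest = core_io.read_manifest(manifest_path)
    design = core_io.read_pair_design(pair_design)
    diffs = pairmodel.compute_pair_differences(betas, design)
    table = pairmodel.fit_cpg_models(diffs, design, min_pairs=min_pairs)
    table = pairmodel.call_dmps(table, covariates=pairmodel.EXPOSURES)
    table = table.join(pairmodel.fold_changes(betas, design))
    loc = manifest.table.set_index("probe_id")[["chrom", "pos"]]
    loc.join(table, how="right").to_csv(out, sep="\t", na_rep="NA")
    click.echo(f"wrote {len(table)} probe statistics to {out}")


@cli.command(name="dmr")
@click.option("--beta-matrix", type=click.Path(exists=True), required=True)
@click.option("--manifest", "manifest_path", type=click.Path(exists=True), required=True)
@click.option("--pair-design", type=click.Path(exists=True), required=True)
@click.option("--out-dir", type=click.Path(), required=True)
@click.option("--seed", type=int, required=True)
@click.option("--n-perm", type=int, default=1000, show_default=True)
@click.option("--maxgap", type=int, default=500, show_default=True)
@click.option("--bandwidth", type=int, default=1000, show_default=True)
@click.option("--quantile", type=float, default=0.99, show_default=True)
@click.option("--surfaces", type=str, default="alpha,smoking,accp,dmard", show_default=True)
def dmr_command(beta_matrix, manifest_path, pair_design, out_dir, seed, n_perm, maxgap, bandwidth, quantile, surfaces):
    """Bump hunting with permutation inference per surface."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    betas = core_io.read_beta_matrix(beta_matrix)
    manifest = core_io.read_manifest(manifest_path)
    design = core_io.read_pair_design(pair_design)
    config = dmr_mod.DMRConfig(maxgap=maxgap, bandwidth=bandwidth, quantile_level=quantile, n_perm=n_perm)
    tables = dmr_mod.covariate_dmrs(
        betas, design, manifest, [s.strip() for s in surfaces.split(",")], config, seed=seed
    )
    for surface, table in tables.items():
        table.drop(columns=["start_idx", "end_idx"]).to_csv(out / f"dmr_{surface}.tsv", sep="\t", index=False)
        click.echo(f"{surface}: {len(table)} putative DMRs")


@cli.command(name="annotate")
@click.option("--dmr-table", type=click.Path(exists=True), required=True)
@click.option("--genes-bed", type=click.Path(exists=True), required=True)
@click.option("--out", type=click.Path(), required=True)
@click.option("--max-distance", type=int, default=100_000, show_default=True)
def annotate_command(dmr_table, genes_bed, out, max_distance):
    """Attach overlapping/nearest genes to a DMR table."""
    table = pd.read_csv(dmr_table, sep="\t", comment="#")
    genes = core_io.read_bed(genes_bed)
    regions = [
        core_io.GenomicRegion(chrom=str(r.chrom), start=int(r.start), end=int(r.end), n_probes=int(r.n_probes))
        for r in table.itertuples()
    ]
    ann = annotate_mod.nearest_gene(regions, genes, max_distance)
    table.assign(gene=ann["gene"].to_numpy(), gene_distance=ann["distance"].to_numpy()).to_csv(
        out, sep="\t", index=False
    )
    click.echo(f"annotated {len(table)} regions")


if __name__ == "__main__":
    cli()
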