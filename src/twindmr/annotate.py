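"""Region-to-gene annotation and the probes-per-gene bias diagnostic.

Candidate regions are annotated with every overlapping gene, or failing
that the nearest gene within a distance cutoff (default 100 kb), echoing
"nearest gene(s) in region" style reporting. Enrichment itself is delegated
to an external regulatory-domain service; this module prepares its BED input
(via :mod:`twindmr.core_io`) and checks its output for the classic array
bias: genes covered by more probes get more chances to appear differentially
methylated, so pathway significance should not correlate with the mean
probes-per-gene of pathway members. The diagnostic is a Spearman correlation
with a pathway-label permutation p-value.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from twindmr.core_io import GenomicRegion, ProbeManifest

logger = logging.getLogger(__name__)

NO_NEARBY_GENE = "no nearby gene"


def nearest_gene(
    regions: Sequence[GenomicRegion],
    genes: pd.DataFrame,
    max_distance: int = 100_000,
) -> pd.DataFrame:
    """Annotate each region with overlapping genes, else the nearest one.

    ``genes`` uses 1-based inclusive coordinates (as returned by
    :func:`twindmr.core_io.read_bed`) with columns chrom/start/end/name.
    Every input region appears exactly once in the output; multiple
    overlapping genes are comma-joined; regions farther than
    ``max_distance`` from any gene (or on a chromosome absent from the gene
    table) are labelled "no nearby gene".
    """
    by_chrom = {c: t.reset_index(drop=True) for c, t in genes.groupby("chrom")}
    records = []
    for region in regions:
        chrom_genes = by_chrom.get(region.chrom)
        name, distance = NO_NEARBY_GENE, np.nan
        if chrom_genes is not None and len(chrom_genes):
            gs = chrom_genes["start"].to_numpy()
            ge = chrom_genes["end"].to_numpy()
            overlap = (gs <= region.end) & (ge >= region.start)
            if overlap.any():
                name = ",".join(chrom_genes.loc[overlap, "name"])
                distance = 0
            else:
                dist = np.maximum(gs - region.end, region.start - ge)
                j = int(np.argmin(dist))
                if dist[j] <= max_distance:
                    name = chrom_genes["name"].iloc[j]
                    distance = int(dist[j])
        records.append(
            {
                "chrom": region.chrom,
                "start": region.start,
                "end": region.end,
                "n_probes": region.n_probes,
                "gene": name,
                "distance": distance,
            }
        )
    return pd.DataFrame(records, columns=["chrom", "start", "end", "n_probes", "gene", "distance"])


def probes_per_gene(manifest: ProbeManifest) -> pd.Series:
    """Number of manifest probes per gene label (empty labels ignored)."""
    genes = manifest.table["gene"]
    counts = genes[genes != ""].value_counts()
    counts.name = "n_probes"
    return counts


def probes_per_gene_bias(
    pathways: pd.DataFrame,
    manifest: ProbeManifest,
    n_perm: int = 10_000,
    seed: int | None = 0,
) -> dict:
    """Correlation between pathway significance and mean probes-per-gene.

    ``pathways`` has columns ``pathway_id``, ``significance`` (a p-value or
    FDR) and ``genes`` (comma-separated symbols). Pathways with no gene
    resolvable against the manifest's gene labels are dropped with a log
    message. Returns the Spearman rho between -log10(significance) and the
    per-pathway mean probes-per-gene, a two-sided permutation p-value over
    ``n_perm`` pathway-label shuffles, and the per-pathway table. Being
    rank-based, the diagnostic is invariant to monotone transformations of
    the significance column; with zero variance in either column rho is 0 by
    convention.
    """
    ppg = probes_per_gene(manifest)
    rows = []
    for row in pathways.itertuples():
        members = [g.strip() for g in str(row.genes).split(",") if g.strip()]
        resolved = [g for g in members if g in ppg.index]
        if not resolved:
            logger.info("pathway %r dropped: no genes resolvable in manifest", row.pathway_id)
            continue
        rows.append(
            {
                "pathway_id": row.pathway_id,
                "significance": float(row.significance),
                "neg_log10_significance": -np.log10(max(float(row.significance), 1e-300)),
                "mean_probes_per_gene": float(ppg.loc[resolved].mean()),
                "n_genes_resolved": len(resolved),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["pathway_id", "significance", "neg_log10_significance", "mean_probes_per_gene", "n_genes_resolved"],
    )
    if len(table) < 3:
        return {"rho": 0.0, "perm_p": 1.0, "table": table}

    x = table["neg_log10_significance"].to_numpy()
    y = table["mean_probes_per_gene"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"rho": 0.0, "perm_p": 1.0, "table": table}
    rho = float(stats.spearmanr(x, y).statistic)

    # permutation null: shuffle which pathway carries which significance
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.linalg.norm(rx_c) * np.linalg.norm(ry_c)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(rx_c, (n_perm, 1)), axis=1)
    null_rho = perms @ ry_c / denom
    perm_p = float((np.abs(null_rho) >= abs(rho) - 1e-12).mean())
    return {"rho": rho, "perm_p": perm_p, "table": table}


def filter_enrichment_table(
    table: pd.DataFrame,
    min_fold: float = 2.0,
    max_fdr: float = 0.05,
    fold_cols: Sequence[str] = ("binom_fold", "hyper_fold"),
    fdr_cols: Sequence[str] = ("binom_fdr", "hyper_fdr"),
) -> pd.DataFrame:
    """Post-filter an external enrichment table: fold enrichment of at least
    ``min_fold`` by either test and FDR below ``max_fdr`` by both tests."""
    fold_ok = np.zeros(len(table), dtype=bool)
    for col in fold_cols:
        fold_ok |= table[col].to_numpy() >= min_fold
    fdr_ok = np.ones(len(table), dtype=bool)
    for col in fdr_cols:
        fdr_ok &= table[col].to_numpy() < max_fdr
    return table.loc[fold_ok & fdr_ok].reset_index(drop=True)
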