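"""Hunt differentially methylated regions on all four coefficient surfaces.

Smooths each per-CpG coefficient surface (disease intercept, smoking,
anti-CCP, DMARD slopes) within probe clusters, thresholds at the 99th
percentile, scores candidate regions by area, and attaches permutation
inference (FWER, suggestive, empirical p, FDR) from within-pair label
swaps. Writes one ranked table and one BED per surface under results/.
"""

import argparse

from common import DEFAULT_SEED, N_PERM, RESULTS, dataset_dir, ensure_dirs
from twindmr import core_io
from twindmr.dmr import DMRConfig, bumps_to_regions, covariate_dmrs


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=DEFAULT_SEED)
    parser.add_argument("--n-perm", type=int, default=N_PERM)
    args = parser.parse_args()
    ensure_dirs(args.seed)
    data = dataset_dir(args.seed)

    betas = core_io.read_beta_matrix(data / "beta_adjusted.tsv")
    manifest = core_io.read_manifest(data / "manifest.tsv")
    design = core_io.read_pair_design(data / "design.tsv")

    config = DMRConfig(n_perm=args.n_perm)
    tables = covariate_dmrs(betas, design, manifest, config=config, seed=args.seed + 10)

    for surface, table in tables.items():
        export = table.drop(columns=["start_idx", "end_idx"])
        export.to_csv(RESULTS / f"04_dmr_{surface}.tsv", sep="\t", index=False, float_format="%.5g")
        core_io.write_bed(
            bumps_to_regions(table),
            scores=table["area"].tolist(),
            names=[f"{surface}_dmr_{r}" for r in table["rank"]],
            path=RESULTS / f"04_dmr_{surface}.bed",
        )
        n_sig = int((table["fwer_p"] < 0.05).sum())
        n_sug = int(table["suggestive"].sum())
        print(f"{surface:8s}: {len(table):3d} putative DMRs, {n_sig} FWER<0.05, {n_sug} suggestive")
        if len(table):
            top = table.iloc[0]
            print(
                f"          top: {top['chrom']}:{top['start']}-{top['end']} "
                f"({top['n_probes']} probes, {top['direction']}), area={top['area']:.3f}, "
                f"fwer_p={top['fwer_p']:.3f}, emp_p={top['emp_p']:.4f}, fold_change={top['fold_change']:.2f}"
            )


if __name__ == "__main__":
    main()
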