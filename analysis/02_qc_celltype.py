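"""QC the simulated betas and remove cell-composition effects.

Applies the strict detection-p > 0.01 masking and the strict >5% probe
missingness filter, estimates leukocyte proportions against the reference
panel by simplex-constrained least squares, and residualizes them out.
Writes the adjusted matrix to scratch/ and a QC summary to
results/02_qc_summary.tsv.
"""

import argparse

import pandas as pd

from common import DEFAULT_SEED, RESULTS, dataset_dir, ensure_dirs
from twindmr import core_io, qc
from twindmr.celltype import CellTypeReference, adjust_for_celltype, estimate_proportions


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=DEFAULT_SEED)
    args = parser.parse_args()
    ensure_dirs(args.seed)
    data = dataset_dir(args.seed)

    betas = core_io.read_beta_matrix(data / "beta.tsv")
    detp = core_io.read_beta_matrix(data / "detp.tsv")
    n_in = betas.n_probes

    masked = qc.mask_by_detection(betas, detp.values, threshold=0.01)
    n_masked = int(masked.missing_mask.sum() - betas.missing_mask.sum())
    filtered, dropped = qc.filter_high_missing(masked, max_missing_frac=0.05)

    ref_frame = pd.read_csv(data / "celltype_reference.tsv", sep="\t", index_col=0)
    ref = CellTypeReference(
        probe_ids=[str(i) for i in ref_frame.index],
        cell_types=[str(c) for c in ref_frame.columns],
        profiles=ref_frame.to_numpy(dtype=float),
    )
    props = estimate_proportions(filtered, ref)
    adjusted = adjust_for_celltype(filtered, props)
    core_io.write_beta_matrix(adjusted, data / "beta_adjusted.tsv")

    summary = pd.DataFrame(
        {
            "step": ["input_probes", "detection_masked_cells", "probes_dropped", "probes_out"],
            "count": [n_in, n_masked, len(dropped), adjusted.n_probes],
        }
    )
    summary.to_csv(RESULTS / "02_qc_summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))
    print(f"mean estimated proportions:\n{props.mean().round(3).to_string()}")
    print(f"wrote adjusted matrix to {data / 'beta_adjusted.tsv'}")


if __name__ == "__main__":
    main()
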