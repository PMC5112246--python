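"""Shared paths and settings for the numbered analysis scripts.

The scripts form one narrative: simulate a 28-pair discordant-twin cohort,
QC it, adjust for cell composition, fit the per-CpG pair model, hunt DMRs
on all four coefficient surfaces, and annotate the hits. Bulky intermediate
data live under scratch/ (regenerated on demand); summary tables land under
results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

DEFAULT_SEED = 1
N_PERM = 200  # scaled-down permutation count for the desk-scale genome


def dataset_dir(seed: int) -> Path:
    return SCRATCH / f"dataset_seed{seed}"


def ensure_dirs(seed: int) -> None:
    dataset_dir(seed).mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)
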