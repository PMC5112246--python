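import numpy as np
import pandas as pd
import pytest

from twindmr.core_io import BetaMatrix, PairDesign, ProbeManifest


@pytest.fixture
def small_design() -> PairDesign:
    """Four complete pairs with both exposure patterns represented."""
    return PairDesign(
        pd.DataFrame(
            {
                "pair_id": ["p1", "p2", "p3", "p4"],
                "case_sample": ["c1", "c2", "c3", "c4"],
                "control_sample": ["k1", "k2", "k3", "k4"],
                "smoking": [1.0, 0.0, 1.0, 0.0],
                "accp": [1, 1, 0, 0],
                "dmard": [0, 1, 1, 0],
                "age": [50.0, 60.0, 55.0, 45.0],
                "sex": [1, 0, 1, 0],
            }
        )
    )


@pytest.fixture
def small_manifest() -> ProbeManifest:
    return ProbeManifest(
        pd.DataFrame(
            {
                "probe_id": [f"cg{i}" for i in range(6)],
                "chrom": ["chr1"] * 6,
                "pos": [100, 300, 550, 2000, 2100, 9000],
                "gene": ["GENEA", "GENEA", "", "GENEB", "GENEB", ""],
            }
        )
    )


@pytest.fixture
def small_betas(small_design, small_manifest) -> BetaMatrix:
    rng = np.random.default_rng(7)
    samples = []
    for row in small_design.table.itertuples():
        samples.extend([row.case_sample, row.control_sample])
    values = np.clip(rng.normal(0.5, 0.1, size=(6, 8)), 0, 1)
    return BetaMatrix(list(small_manifest.probe_ids), samples, values)
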