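import numpy as np
import pandas as pd
import pytest

from circatx.datamodel import ExpressionSet
from circatx.simulate import SimConfig, simulate_expression

ZT_GRID = np.array([2.0, 6.0, 10.0, 14.0, 18.0, 22.0])


@pytest.fixture(scope="session")
def times_4rep():
    """The emulated sampling design: 6 timepoints x 4 replicates."""
    return np.tile(ZT_GRID, 4)


@pytest.fixture()
def tiny_es():
    """Hand-written 3-feature x 4-sample set for I/O round trips."""
    samples = pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "group": ["CON"] * 4,
        "zt": [2.0, 8.0, 14.0, 20.0],
        "replicate": [1, 1, 1, 1],
    })
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 5.5, 6.0, 6.5], [0.1, 0.2, 0.3, 0.4]],
        index=["pA", "pB", "pC"], columns=samples["sample_id"],
    )
    return ExpressionSet(values, samples)


@pytest.fixture(scope="session")
def small_sim():
    """Small synthetic dataset with planted effects of every class."""
    cfg = SimConfig(n_features=60, n_mesor_up=5, n_mesor_down=5,
                    n_amp_change=5, n_phase_shift=5, n_tuning_opposite=6,
                    noise_sd=0.2, frac_rhythmic=0.5, seed=11)
    sets, truth = simulate_expression(cfg)
    return cfg, sets, truth


def write_es(es: ExpressionSet, tmpdir, prefix="x"):
    """Write an ExpressionSet to matrix TSV + sheet CSV; return the paths."""
    mat = tmpdir / f"{prefix}_matrix.tsv"
    sheet = tmpdir / f"{prefix}_sheet.csv"
    out = es.values.copy()
    out.insert(0, "feature", out.index)
    out.to_csv(mat, sep="\t", index=False)
    es.samples.to_csv(sheet, index=False)
    return mat, sheet
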