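import numpy as np
import pandas as pd
import pytest

from bafcnv.core import CoverageModel
from bafcnv.simulate import SimSpec, generate_panel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_table(chrom, pos, depth_control, alt_control, depth_case, alt_case):
    n = len(pos)
    return pd.DataFrame(
        {
            "chrom": [chrom] * n if isinstance(chrom, str) else chrom,
            "pos": pos,
            "ref": ["A"] * n,
            "alt": ["T"] * n,
            "depth_control": depth_control,
            "alt_control": alt_control,
            "depth_case": depth_case,
            "alt_case": alt_case,
        }
    )


@pytest.fixture(scope="session")
def null_panel():
    """Matched pair with no implanted events, ~40 Mb, depth ~100x."""
    spec = SimSpec(
        chrom_lengths={"1": 40_000_000},
        snp_density=10.0,
        seed=77,
    )
    table, truth = generate_panel(spec)
    return table, truth


@pytest.fixture(scope="session")
def deletion_panel():
    """One clonal 12 Mb deletion at CF 0.9 on a 40 Mb chromosome."""
    spec = SimSpec(
        chrom_lengths={"1": 40_000_000},
        snp_density=10.0,
        cnvs=[("1", 10_000_000, 22_000_000, "deletion", 0.9)],
        seed=78,
    )
    table, truth = generate_panel(spec)
    return spec, table, truth


@pytest.fixture(scope="session")
def flat_coverage():
    return CoverageModel(meanlog=float(np.log(500.0)), sdlog=1e-6)
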