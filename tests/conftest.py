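import numpy as np
import pandas as pd
import pytest

from sohscan.simulate import (
    GenomeSimConfig,
    PanelSimConfig,
    simulate_genome_profile,
    simulate_species_panel,
)
from sohscan.vcfio import VariantRecord


@pytest.fixture(scope="session")
def default_genome():
    """One ~30 Mb simulated genome under the default study conditions."""
    return simulate_genome_profile(GenomeSimConfig(seed=1))


@pytest.fixture(scope="session")
def default_panel():
    """A 105-species panel under the default study conditions."""
    return simulate_species_panel(PanelSimConfig(seed=1))


def make_het_record(scaffold="s1", pos=100, gq=99, dp=40, ad=None, genotype="het"):
    if ad is None and dp is not None:
        ad = (dp // 2, dp - dp // 2)
    return VariantRecord(
        scaffold=scaffold, pos=pos, ref="A", alt="G",
        genotype=genotype, gq=gq, dp=dp, ad=ad,
    )


@pytest.fixture
def scaffold_table():
    return pd.DataFrame({
        "scaffold": ["s1", "s2", "s3"],
        "length": [120_000, 35_000, 15_000],
        "mean_depth": [40.0, 40.0, 40.0],
    })


def n50(lengths) -> int:
    ln = np.sort(np.asarray(lengths))[::-1]
    csum = np.cumsum(ln)
    return int(ln[np.searchsorted(csum, csum[-1] / 2)])
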