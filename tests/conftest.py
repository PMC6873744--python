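import numpy as np
import pytest
from hypothesis import settings

import telomr as t

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def packaged_records():
    """All 16 packaged exposure/outcome instrument records."""
    return t.load_packaged_instruments()


@pytest.fixture(scope="session")
def packaged_ld(packaged_records):
    exposure, _ = packaged_records
    return t.simulate_ld_blocks(exposure, t.locus_blocks(exposure))


@pytest.fixture(scope="session")
def packaged_clump(packaged_records, packaged_ld):
    exposure, _ = packaged_records
    return t.greedy_clump(exposure, packaged_ld)


def _panel(packaged_records, packaged_clump, convention):
    exposure, outcome = packaged_records
    kept = set(packaged_clump.kept)
    harmonized = t.harmonize_tables(
        [r for r in exposure if r.snp_id in kept], outcome
    )
    return t.build_panel(harmonized, sign_convention=convention)


@pytest.fixture(scope="session")
def study_panel(packaged_records, packaged_clump):
    """The 10 retained instruments, reported per SD decrease of exposure."""
    return _panel(packaged_records, packaged_clump, "per_sd_decrease")


@pytest.fixture(scope="session")
def study_panel_increase(packaged_records, packaged_clump):
    return _panel(packaged_records, packaged_clump, "per_sd_increase")


@pytest.fixture()
def random_panel():
    """A moderately heterogeneous synthetic panel for property tests."""
    panel, _ = t.simulate_panel(
        t.SimulationConfig(
            n_snps=12, beta_true=0.03, pleiotropy_mode="balanced",
            prop_invalid=0.25, pleiotropy_sd=0.002, seed=314,
        )
    )
    return panel


def round_sig(x: float, digits: int = 2) -> float:
    """Round to a number of significant figures."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + digits - 1)
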