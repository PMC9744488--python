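import numpy as np
import pytest

from prnai.qpcr import Amplicon, DsRnaRegion
from prnai.simulate import ExpressionProfileSpec, SimConfig, simulate_qpcr


@pytest.fixture(scope="session")
def unimodal_profile():
    """Single early expression pulse peaking at 8 h (serosa-specifier style)."""
    return ExpressionProfileSpec("unimodal_pulse", (8.0,), (4.0,), 1.0)


@pytest.fixture(scope="session")
def dsrna_region():
    return DsRnaRegion("tgt", 101, 788)


@pytest.fixture(scope="session")
def amplicon_set(dsrna_region):
    """One semi-nested, one nested target amplicon plus the reference."""
    return [
        Amplicon("semi", "tgt", 60, 160),     # straddles the region start
        Amplicon("nested", "tgt", 300, 420),  # fully inside
        Amplicon("ref", "ref_gene", 1, 120),
    ]


@pytest.fixture(scope="session")
def noiseless_experiment(unimodal_profile, dsrna_region, amplicon_set):
    """Noiseless simulated qPCR experiment over four stage windows."""
    config = SimConfig(knockdown_k=0.05, dsrna_level=0.25,
                       sigma_cp=0.0, sigma_bio=0.0, seed=1)
    stages = [(4, 8), (8, 16), (16, 24), (24, 48)]
    tables = simulate_qpcr(unimodal_profile, amplicon_set, dsrna_region,
                           stages, config)
    return {"tables": tables, "config": config, "stages": stages,
            "profile": unimodal_profile}
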