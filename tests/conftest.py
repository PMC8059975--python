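import numpy as np
import pytest

import bryoparent as bp


@pytest.fixture(scope="session")
def small_panel() -> bp.ParentPanel:
    """2 males x 3 females, 2 loci x 2 SNPs — tiny but fully resolvable."""
    return bp.simulate_panel(2, 3, n_loci=2, locus_length=200, snps_per_locus=2, seed=101)


@pytest.fixture(scope="session")
def study_panel() -> bp.ParentPanel:
    """The experiment-like panel: 6 males, 9 females, 5 loci x 3 SNPs."""
    return bp.simulate_panel(6, 9, seed=7)


@pytest.fixture(scope="session")
def study_cross(study_panel):
    design = bp.MesocosmDesign(
        female_ids=study_panel.females(),
        male_ids=study_panel.males(),
        n_sporophytes=12,
    )
    truth = bp.simulate_crosses(study_panel, design, seed=8)
    return design, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
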