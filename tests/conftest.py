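import numpy as np
import pytest

from hybridzone import PanelConfig, simulate_individuals, simulate_panel


@pytest.fixture(scope="session")
def default_panel():
    """The seven-locus study panel (5 private @0.7, 2 shared @0.8/0.2)."""
    return simulate_panel(PanelConfig())


@pytest.fixture(scope="session")
def diagnostic_panel():
    """Fully diagnostic panel: private alleles at frequency 1.0."""
    return simulate_panel(
        PanelConfig(n_loci_private=7, private_allele_freq=1.0, n_loci_variable=0)
    )


@pytest.fixture(scope="session")
def parental_tables(default_panel):
    """Reference parental samples (25 per species) split by species."""
    table = simulate_individuals(default_panel, 25, seed=2024)
    sp_a, sp_b = default_panel.species
    ref_a = table[table.species == sp_a].reset_index(drop=True)
    ref_b = table[table.species == sp_b].reset_index(drop=True)
    return ref_a, ref_b


@pytest.fixture()
def rng():
    return np.random.default_rng(99)


def panel_freq_mappings(panel):
    """True allele-frequency mappings of a panel (for exact posteriors)."""
    fa = {l: dict(zip(panel.alleles[l].tolist(), panel.freq_a[l])) for l in panel.loci}
    fb = {l: dict(zip(panel.alleles[l].tolist(), panel.freq_b[l])) for l in panel.loci}
    return fa, fb
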