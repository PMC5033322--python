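from pathlib import Path

import pytest

from clademark.simulate import CladeSimConfig, simulate_clade

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def reference_panel_path() -> Path:
    """Published 26-strain B. pumilus-group panel: 24 group strains with
    train/test roles plus two comparison outgroups."""
    return DATA / "bpumilus_panel_strains.tsv"


@pytest.fixture(scope="session")
def small_clade():
    """3 species x 3 strains, 1%/8% divergence, 6 core genes + filler."""
    cfg = CladeSimConfig(
        n_species=3,
        strains_per_species=3,
        n_core_genes=6,
        gene_length_range=(300, 450),
        within_species_divergence=0.01,
        between_species_divergence=0.08,
        filler_length=400,
        seed=42,
    )
    return simulate_clade(cfg)


@pytest.fixture(scope="session")
def four_species_clade():
    """4 species x 3 strains without filler, for cluster-recovery checks."""
    cfg = CladeSimConfig(
        n_species=4,
        strains_per_species=3,
        n_core_genes=6,
        gene_length_range=(300, 450),
        within_species_divergence=0.01,
        between_species_divergence=0.08,
        filler_length=0,
        seed=11,
    )
    return simulate_clade(cfg)
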