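import numpy as np
import pytest

from panelcov.intervals import (
    CaptureDesign,
    Exon,
    GenePanel,
    GenomicInterval,
)
from panelcov.io import DepthProfile
from panelcov.simulate import SimulationConfig, simulate


@pytest.fixture
def tiny_panel() -> GenePanel:
    """Two genes, four exons; GB's exons overlap to exercise multi-exon
    positions."""
    exons = [
        Exon(GenomicInterval("chr1", 10, 20), "GA", "GA_e1"),
        Exon(GenomicInterval("chr1", 100, 160), "GA", "GA_e2"),
        Exon(GenomicInterval("chr2", 50, 90), "GB", "GB_e1"),
        Exon(GenomicInterval("chr2", 80, 120), "GB", "GB_e2"),
    ]
    return GenePanel(["GA", "GB"], exons)


@pytest.fixture
def tiny_design() -> CaptureDesign:
    """Targets everything except GA_e2 (dropped) and trims nothing."""
    return CaptureDesign(
        [
            GenomicInterval("chr1", 10, 20),
            GenomicInterval("chr2", 50, 120),
        ]
    )


@pytest.fixture
def flat_profile(tiny_panel) -> DepthProfile:
    """Uniform depth 25 over the whole footprint."""
    fp = tiny_panel.footprint
    return DepthProfile("S1", fp, np.full(fp.total_bases, 25, dtype=np.int32))


@pytest.fixture(scope="session")
def small_dataset():
    """Seeded desk-scale synthetic dataset shared across tests."""
    cfg = SimulationConfig(
        seed=7,
        n_genes=12,
        n_exons_total=120,
        n_samples=6,
        n_variants_total=600,
        n_cases_unknown=30,
    )
    return simulate(cfg)
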