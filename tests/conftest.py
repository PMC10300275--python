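import numpy as np
import pytest

from panelval.coverage import DepthTrack
from panelval.intervals import GeneModel, GenomicInterval, build_targets
from panelval.simulate import SimulationConfig, simulate_study


@pytest.fixture
def toy_design():
    """Two genes on two chromosomes, flank 25, non-adjacent exons."""
    genes = [
        GeneModel(
            name="GENEA", category="iron overload",
            exons=[GenomicInterval("chr1", 1000, 1200),
                   GenomicInterval("chr1", 2000, 2150)],
        ),
        GeneModel(
            name="GENEB", category="lipid metabolism",
            exons=[GenomicInterval("chr2", 500, 700)],
            extra_regions=[GenomicInterval("chr2", 100, 200)],
        ),
    ]
    return build_targets(genes, flank=25)


def uniform_track(design, depth, sample_id="S1", platform="TS"):
    data = {}
    for chrom in {iv.chrom for iv in design.targets}:
        pos = np.concatenate([np.arange(iv.start, iv.end)
                              for iv in design.targets if iv.chrom == chrom])
        pos.sort()
        data[chrom] = (pos, np.full(len(pos), depth, dtype=np.int64))
    return DepthTrack(sample_id=sample_id, platform=platform, data=data)


@pytest.fixture
def small_sim_config():
    """A fast, fully planted scenario for end-to-end tests."""
    return SimulationConfig(
        seed=7, n_genes=6, exons_per_gene=(2, 5), exon_length=(60, 150),
        n_samples=3, planted_counts=(10, 2, 2, 1, 1), background_counts=(8, 3, 2),
    )


@pytest.fixture
def small_study(small_sim_config):
    return simulate_study(small_sim_config)
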