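import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from transpoly.core import GenotypeMatrix, SampleInfo, SiteRecord

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_gm(
    genotypes,
    species,
    positions=None,
    chrom="chr1",
    annotations=None,
    gene_ids=None,
    mean_depths=None,
    allele_depths=None,
    phased=None,
):
    """Build a GenotypeMatrix from plain arrays (sites x samples)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    positions = positions if positions is not None else np.arange(1, n_sites + 1)
    annotations = annotations or ["unknown"] * n_sites
    gene_ids = gene_ids or [None] * n_sites
    mean_depths = mean_depths if mean_depths is not None else [float("nan")] * n_sites
    sites = [
        SiteRecord(
            chrom=chrom,
            pos=int(positions[i]),
            ref="A",
            alt="T",
            annotation=annotations[i],
            gene_id=gene_ids[i],
            mean_depth=float(mean_depths[i]),
        )
        for i in range(n_sites)
    ]
    samples = [
        SampleInfo(sample_id=f"s{j:03d}", species=species[j], population="pop")
        for j in range(n_samples)
    ]
    return GenotypeMatrix(
        sites=sites,
        samples=samples,
        genotypes=g,
        allele_depths=allele_depths,
        phased_haplotypes=phased,
    )


@pytest.fixture
def two_species_gm():
    """3 sites x 4 samples, two per species, with phase and depths."""
    genotypes = [[0, 1, 2, 1], [1, 1, 0, 0], [2, 2, 0, 0]]
    phased = np.array(
        [[0, 0, 0, 1, 1, 1, 1, 0], [1, 0, 0, 1, 0, 0, 0, 0], [1, 1, 1, 1, 0, 0, 0, 0]],
        dtype=np.int8,
    )
    ad = np.full((3, 4, 2), 5, dtype=np.int32)
    return make_gm(
        genotypes,
        species=["A_sp", "A_sp", "B_sp", "B_sp"],
        mean_depths=[10.0, 12.0, 20.0],
        allele_depths=ad,
        phased=phased,
    )
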