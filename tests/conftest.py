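import numpy as np
import pytest

from foundersweep.core import GenotypeTable, Site
from foundersweep.simulate import DemographicModel

DATA = __file__.rsplit("/", 1)[0] + "/data"


@pytest.fixture(scope="session")
def fitted_model() -> DemographicModel:
    """The maximum-likelihood founder model used throughout."""
    return DemographicModel(N1=35_000, N2b=14.4, N2f=1290, T=50, mu=1e-8)


def make_table(genos, populations=None, chrom="chr1", quals=None, depths=None):
    """Build a GenotypeTable from a (sites x individuals) genotype list."""
    genos = np.asarray(genos, dtype=np.int8)
    n_ind = genos.shape[1]
    samples = [f"s{i}" for i in range(n_ind)]
    if populations is None:
        populations = {"pop1": list(range(n_ind))}
    sites = [
        Site(
            chrom=chrom,
            pos=10 * (j + 1),
            ref="A",
            alt="T",
            qual=50.0 if quals is None else quals[j],
            depth=30.0 if depths is None else depths[j],
            genotypes=genos[j],
        )
        for j in range(genos.shape[0])
    ]
    return GenotypeTable(sites=sites, samples=samples, populations=populations)
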