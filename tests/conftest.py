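import numpy as np
import pytest

from tissueclock import (
    AgeTransform,
    CohortDesign,
    CpGArchetypeSpec,
    CpGLocus,
    FitConfig,
    MethylationMatrix,
    SampleMeta,
    fit_clock,
    simulate_cohort,
    simulate_study,
)


def make_matrix(values, mask=None, ages=None, tissues=None, strains=None,
                chrom="chr1"):
    """Hand-build a small MethylationMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_loci, n_samples = values.shape
    loci = [CpGLocus(id=f"{chrom}:{100 + 10 * i}", chrom=chrom, pos=100 + 10 * i)
            for i in range(n_loci)]
    ages = ages if ages is not None else [3.0 + j for j in range(n_samples)]
    tissues = tissues or ["cortex"] * n_samples
    strains = strains or ["B6"] * n_samples
    samples = [
        SampleMeta(sample_id=f"s{j}", tissue=tissues[j], strain=strains[j],
                   sex="F", age=float(ages[j]))
        for j in range(n_samples)
    ]
    return MethylationMatrix(loci=loci, samples=samples, values=values, mask=mask)


@pytest.fixture(scope="session")
def default_cohort():
    return simulate_cohort(seed=1)


@pytest.fixture(scope="session")
def small_study():
    """A reduced-panel study for fast clock fitting in unit tests."""
    spec = CpGArchetypeSpec(n_null=250, n_age=80, n_tissue=40, n_strain=20,
                            n_interaction=10)
    return simulate_study(design=CohortDesign(n_per_cell=3), spec=spec, seed=11)


@pytest.fixture(scope="session")
def small_cortex_clock(small_study):
    return fit_clock(small_study.training["cortex"], "cortex", AgeTransform(),
                     FitConfig(seed=5))
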