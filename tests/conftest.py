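import pytest

from fxscreen import (
    Allele,
    Genotype,
    NoiseModel,
    TmResponseModel,
    load_reference_cohort,
)


@pytest.fixture(scope="session")
def cohort():
    """The packaged 151-sample reference cohort."""
    return load_reference_cohort()


@pytest.fixture(scope="session")
def tm_model():
    return TmResponseModel()


@pytest.fixture(scope="session")
def noiseless():
    return NoiseModel.noiseless()


def male(n: int, sample_id: str = "m") -> Genotype:
    return Genotype(sample_id=sample_id, sex="M", alleles=(Allele(n),))


def female(a: int, b: int, sample_id: str = "f", mosaic=()) -> Genotype:
    return Genotype(
        sample_id=sample_id,
        sex="F",
        alleles=(Allele(a), Allele(b)),
        mosaic_components=tuple((Allele(m), frac) for m, frac in mosaic),
    )
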