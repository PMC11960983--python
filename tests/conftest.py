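import numpy as np
import pytest

from batmle import (
    CODES,
    ClassifiedNight,
    ConfusionMatrix,
    builtin_profile,
    build_design,
    identity_confusion,
    run_simulation,
    tp_fn_by_count,
)
from batmle.metamodel import fit_all_species

TOY2_SPECIES = ("EPFU", "LABO")


@pytest.fixture(scope="session")
def toy2_cm() -> ConfusionMatrix:
    """Well-separated 2-species classifier with no NOID mass."""
    theta = np.array([[0.9, 0.1, 0.0], [0.2, 0.8, 0.0]])
    return ConfusionMatrix(species=TOY2_SPECIES, theta=theta, name="toy2")


@pytest.fixture(scope="session")
def identity_cm() -> ConfusionMatrix:
    return identity_confusion()


@pytest.fixture(scope="session")
def kpro_cm() -> ConfusionMatrix:
    return builtin_profile("kpro-like")


@pytest.fixture(scope="session")
def design():
    return build_design()


@pytest.fixture(scope="session")
def full_run(design, kpro_cm):
    """Full-design simulation under the default synthetic classifier."""
    return run_simulation(design, kpro_cm, mode="exact")


@pytest.fixture(scope="session")
def summaries(full_run):
    return tp_fn_by_count(full_run)


@pytest.fixture(scope="session")
def fits(full_run):
    return fit_all_species(full_run)


def toy2_night(c0: float, c1: float) -> ClassifiedNight:
    return ClassifiedNight(np.array([c0, c1], dtype=float), species=TOY2_SPECIES)
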