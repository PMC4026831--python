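import numpy as np
import pytest

from myoecv.relaxometry import build_scheme_335
from myoecv.synthetic import (
    LesionSector,
    PhantomGeometry,
    TissueModel,
    generate_subject,
)


@pytest.fixture(scope="session")
def scheme():
    return build_scheme_335(1000.0, (100.0, 180.0, 260.0))


@pytest.fixture(scope="session")
def control_tissue():
    return TissueModel(lambda_remote=0.5, hematocrit=0.48)


@pytest.fixture(scope="session")
def control_subject_noiseless(control_tissue):
    return generate_subject(
        PhantomGeometry(), control_tissue, seed=1, snr=np.inf
    )


@pytest.fixture(scope="session")
def control_subject_snr50(control_tissue):
    return generate_subject(PhantomGeometry(), control_tissue, seed=2, snr=50.0)


def make_lesion_geometry(start_angle: float = 0.0) -> PhantomGeometry:
    return PhantomGeometry(
        lesion_sectors=[
            LesionSector(start_angle, start_angle + 40, 1.0, "lesion_border"),
            LesionSector(start_angle + 40, start_angle + 100, 1.0, "lesion_core"),
            LesionSector(start_angle + 100, start_angle + 140, 1.0, "lesion_border"),
        ]
    )


@pytest.fixture(scope="session")
def lesion_tissue():
    hct = 0.42
    return TissueModel(
        lambda_remote=0.27 / (1 - hct),
        lambda_border=0.35 / (1 - hct),
        lambda_core=0.45 / (1 - hct),
        hematocrit=hct,
    )


@pytest.fixture(scope="session")
def lesion_subject_noiseless(lesion_tissue):
    return generate_subject(
        make_lesion_geometry(), lesion_tissue, seed=3, snr=np.inf
    )


@pytest.fixture(scope="session")
def lesion_subject_snr50(lesion_tissue):
    return generate_subject(make_lesion_geometry(), lesion_tissue, seed=4, snr=50.0)
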