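import pytest

from octmag import EyeBiometry, PitModel, ScanGeometry


@pytest.fixture(scope="session")
def geometry() -> ScanGeometry:
    return ScanGeometry()


@pytest.fixture(scope="session")
def small_geometry() -> ScanGeometry:
    """Laterally downsampled raster for cohort-scale simulations."""
    return ScanGeometry(n_ascans=128, scale_x_default=8.64 / 127)


@pytest.fixture(scope="session")
def dense_geometry() -> ScanGeometry:
    """Near-isotropic dense raster for quadrature-oracle comparisons."""
    return ScanGeometry(n_bscans=512, n_ascans=512,
                        scale_x_default=7.2 / 511,
                        scale_y_default=7.2 / 511)


@pytest.fixture(scope="session")
def pit() -> PitModel:
    return PitModel()


@pytest.fixture()
def od_eye() -> EyeBiometry:
    return EyeBiometry(participant_id="P01", eye="OD", axial_length=22.5,
                       sphere=-2.0, snr=30.0)
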