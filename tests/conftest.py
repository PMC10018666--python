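import numpy as np
import pytest

from rtautoplan import dose_eval, phantom
from rtautoplan.structure_builder import default_hawbrt_config
from rtautoplan.templates import (
    packaged_data_path,
    parse_clinical_protocol,
    parse_structure_dictionary,
)
from rtautoplan.volumetric import SpatialGrid, StructureMask


@pytest.fixture
def unit_grid():
    """16^3 grid, 1 mm isotropic, voxel centers at 0.5, 1.5, ..."""
    return SpatialGrid(origin=(0.5, 0.5, 0.5), spacing=(1, 1, 1), dims=(16, 16, 16))


def random_mask(grid: SpatialGrid, rng: np.random.Generator, p: float = 0.3) -> StructureMask:
    return StructureMask(grid, rng.random(grid.shape_zyx) < p, "random")


@pytest.fixture(scope="session")
def default_phantom():
    spec = phantom.load_default_spec()
    ct, masks = phantom.generate_phantom(spec)
    return spec, ct, masks


@pytest.fixture(scope="session")
def phantom_dose(default_phantom):
    """Default phantom dose, prescription-normalized to D95%(PTV) = 30 Gy."""
    spec, _, masks = default_phantom
    dose = phantom.generate_dose(masks, spec.dose_model)
    dose, scale = dose_eval.normalize_prescription(dose, masks["PTV_3000"], 30.0)
    return dose, scale


@pytest.fixture(scope="session")
def hawbrt_protocol():
    return parse_clinical_protocol(packaged_data_path("hawbrt_protocol.xml").read_text())


@pytest.fixture(scope="session")
def hawbrt_config():
    return default_hawbrt_config()


@pytest.fixture(scope="session")
def structure_dictionary():
    return parse_structure_dictionary(
        packaged_data_path("structure_dictionary.xml").read_text()
    )
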