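import numpy as np
import pytest

from dvhdb.fixtures import (
    Box,
    Cylinder,
    PhantomSpec,
    PlanMeta,
    RingCylinder,
    RxGroupSpec,
    Sphere,
    StructureSpec,
    TwoIslands,
    make_phantom,
    write_dicom_rt,
)


@pytest.fixture
def sphere_phantom():
    """r = 25 mm sphere on a 2 mm grid, uniform 60 Gy."""
    spec = PhantomSpec(
        grid_shape=(34, 40, 40),
        spacing=(2.0, 2.0, 2.0),
        structures=[StructureSpec("PTV_sph", "PTV", Sphere(25.0))],
    )
    return make_phantom(spec)


@pytest.fixture
def box_phantom():
    """40x40x30 mm box, uniform 60 Gy — exact voxel-centre cover on a 2 mm grid."""
    spec = PhantomSpec(
        grid_shape=(21, 30, 30),
        spacing=(2.0, 2.0, 2.0),
        structures=[StructureSpec("PTV_box", "PTV", Box(40.0, 40.0, 30.0))],
    )
    return make_phantom(spec)


@pytest.fixture
def gradient_phantom():
    """Axial dose gradient dose(z) = z/10 + 6 Gy with a centred box."""
    from dvhdb.fixtures import ZGradientDose

    spec = PhantomSpec(
        grid_shape=(20, 24, 24),
        spacing=(2.0, 2.0, 2.0),
        dose_model=ZGradientDose(slope=0.1, offset=6.0),
        structures=[StructureSpec("target", "PTV", Box(30.0, 30.0, 30.0))],
    )
    return make_phantom(spec)


@pytest.fixture
def complete_fileset(tmp_path):
    """A written-and-discovered DICOM-RT trio of a simple two-structure plan."""
    from dvhdb.ingest import discover_filesets

    spec = PhantomSpec(
        grid_shape=(24, 40, 40),
        structures=[
            StructureSpec("PTV_1", "PTV", Sphere(15.0)),
            StructureSpec("cord", "ORGAN", Cylinder(5.0, 20.0), (0.0, 20.0, 0.0)),
        ],
        plan_meta=PlanMeta(mrn="PX01", tx_site="Brain"),
        seed=7,
    )
    write_dicom_rt(spec, out_dir=tmp_path, seed=7)
    filesets, incomplete = discover_filesets(tmp_path)
    assert not incomplete and len(filesets) == 1
    return spec, filesets[0]
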