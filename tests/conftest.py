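import numpy as np
import pytest

import connectoscan as cs


@pytest.fixture(scope="session")
def gtab():
    return cs.default_gradient_table()


@pytest.fixture(scope="session")
def straight_phantom(gtab):
    spec = cs.phantoms.straight_bundle_spec()
    dwi, truth, labels = cs.make_bundle_phantom(spec, gtab)
    return {"spec": spec, "dwi": dwi, "truth": truth, "labels": labels}


@pytest.fixture(scope="session")
def straight_field(straight_phantom, gtab):
    return cs.fit_tensor(straight_phantom["dwi"], gtab)


@pytest.fixture(scope="session")
def straight_tract(straight_field):
    return cs.track_whole_volume(straight_field)


@pytest.fixture(scope="session")
def bend_phantom(gtab):
    spec = cs.phantoms.sharp_bend_spec()
    dwi, truth, labels = cs.make_bundle_phantom(spec, gtab)
    field = cs.fit_tensor(dwi, gtab)
    tract = cs.track_whole_volume(field)
    return {"spec": spec, "truth": truth, "labels": labels,
            "field": field, "tract": tract}


@pytest.fixture(scope="session")
def planted_cohort():
    return cs.make_cohort(cs.CohortSpec(seed=7))


def uniform_tensor_field(shape=(10, 10, 10), eigenvalues=(3e-3, 1e-3, 1e-3),
                         axis=(1.0, 0.0, 0.0), voxel_mm=2.0):
    """Homogeneous tensor field with principal axis along ``axis``."""
    from connectoscan.phantoms import _tensor_along

    D = np.tile(_tensor_along(np.asarray(axis, float), eigenvalues),
                shape + (1, 1))
    affine = np.diag([voxel_mm] * 3 + [1.0])
    return cs.TensorField(D=D, affine=affine)
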