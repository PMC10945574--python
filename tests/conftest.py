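import pytest

from nmquant import synthetic_data as sd


@pytest.fixture(scope="session")
def clean_muscle_phantom():
    """Zero-noise, zero-PSF muscle phantom: analytic truth is exact."""
    spec = sd.MusclePhantomSpec(
        n_fibers=10, psf_sigma_um=0.0, poisson_scale=0.0, gaussian_sd=0.0, seed=11
    )
    vol, truth = sd.generate_muscle_phantom(spec)
    return spec, vol, truth


@pytest.fixture(scope="session")
def clean_nerve_phantom():
    spec = sd.NervePhantomSpec(
        n_axons=80, psf_sigma_um=0.0, poisson_scale=0.0, gaussian_sd=0.0, seed=7
    )
    vol, table = sd.generate_nerve_phantom(spec)
    return spec, vol, table


@pytest.fixture(scope="session")
def trace_spec():
    return sd.TracePhantomSpec(seed=5)


def cylinder_volume(radius_um=8.0, voxel=(0.5, 0.5, 0.5), ny=64, nz=64, nx=48, axis=None):
    """A zero-noise circular cylinder along ``axis`` (default +x), centred in y/z."""
    if axis is None:
        axis = (1.0, 0.0, 0.0)
    return sd.generate_cylinder_volume(
        radius_um=radius_um, axis=axis, voxel_size_um=voxel, shape_zyx=(nz, ny, nx)
    )
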