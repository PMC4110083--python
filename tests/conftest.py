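"""Shared fixtures: small phantoms and synthetic livers, computed once."""

from __future__ import annotations

import numpy as np
import pytest

from hepavessel import (
    Mask,
    PipelineConfig,
    TubePhantomSpec,
    make_tube_phantom,
    remove_bias,
    resample_isotropic,
    resample_to_spacing,
)
from hepavessel.phantom import SyntheticLiverSpec, make_synthetic_liver
from hepavessel.vesselness import frangi_multiscale, scales_for_radius

# the five pixels-per-diameter study points: (tube diameter mm, in-plane mm)
RESOLUTION_PAIRS = [(4, 1.56), (6, 1.56), (8, 1.56), (6, 1.04), (8, 1.04)]


def vesselness_map(volume, ppd):
    """De-bias, resample isotropic, filter at tube-radius scales, resample back."""
    config = PipelineConfig(sigma_list=scales_for_radius(ppd / 2.0))
    iso = resample_isotropic(remove_bias(volume))
    nu = frangi_multiscale(iso, config)
    back = resample_to_spacing(nu, volume.spacing, shape=volume.shape)
    return back.copy_with(np.clip(back.data, 0.0, 1.0))


@pytest.fixture(scope="session")
def tube_case():
    """A 6 mm perpendicular tube at 1.56 mm with its vesselness map."""
    spec = TubePhantomSpec(tube_diameter_mm=6.0, in_plane_resolution_mm=1.56, seed=7)
    vol, truth = make_tube_phantom(spec)
    full = Mask(np.ones(vol.shape, dtype=np.uint8), vol.spacing)
    nu = vesselness_map(vol, spec.tube_diameter_mm / spec.in_plane_resolution_mm)
    return {"spec": spec, "volume": vol, "truth": truth, "mask": full, "vesselness": nu}


@pytest.fixture(scope="session")
def liver_case():
    """Synthetic liver: 6 mm main vessel plus a separate 2 mm twig."""
    shape, spacing = (64, 64, 28), (1.2, 1.2, 2.4)
    main = ((38.0, 38.0, 8.0), (38.0, 38.0, 59.0), 3.0)
    twig = ((52.0, 38.0, 16.0), (52.0, 38.0, 52.0), 1.0)
    spec = SyntheticLiverSpec(
        volume_shape=shape,
        spacing=spacing,
        vessel_tree=(main, twig),
        noise_sd=2.0,
        bias_amplitude=0.2,
        seed=1,
    )
    vol, liver, truth = make_synthetic_liver(spec)
    return {"spec": spec, "volume": vol, "liver": liver, "truth": truth,
            "main": main, "twig": twig}


@pytest.fixture(scope="session")
def liver_config():
    """Pipeline configuration with scales matched to the largest (3 mm radius) vessel."""
    return PipelineConfig(sigma_list=scales_for_radius(3.0 / 1.2))
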