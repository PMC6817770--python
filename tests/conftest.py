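import warnings

import numpy as np
import pytest

from vesselmorph import (
    PixelCalibration,
    PopulationSpec,
    SegmentedVessel,
    SyntheticVesselSpec,
    make_vessel,
    measure,
    sample_population,
)


@pytest.fixture(scope="session")
def default_population():
    """One default two-group study (81 + 31 vessels) at a fixed seed."""
    return sample_population(PopulationSpec(master_seed=2024))


@pytest.fixture(scope="session")
def default_measurements(default_population):
    """Morphometry records for the shared default population."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # estimator-disagreement notices
        return [(measure(v), t) for v, t in default_population]


@pytest.fixture
def annulus_5_8():
    """Circular vessel: lumen radius 5 μm, wall 3 μm, at 0.05 μm/px."""
    spec = SyntheticVesselSpec(lumen_semi_axes=(5.0, 5.0), wall_thickness_base=3.0)
    vessel, truth = make_vessel(spec, 0.05, 400)
    return vessel, truth


@pytest.fixture
def annulus_1_2():
    """Small ring: lumen radius 1 μm, wall 1 μm, fine grid (0.02 μm/px)."""
    spec = SyntheticVesselSpec(lumen_semi_axes=(1.0, 1.0), wall_thickness_base=1.0)
    vessel, truth = make_vessel(spec, 0.02, 260)
    return vessel, truth


def rectangular_vessel(
    lumen_px: tuple[int, int],
    outer_px: tuple[int, int],
    microns_per_pixel: float,
    vessel_id: str = "rect",
    trim_wall_px: int = 0,
    **flags,
) -> SegmentedVessel:
    """Hand-built rectangular vessel with exact pixel counts.

    The lumen is a centred ``lumen_px`` rectangle inside an ``outer_px``
    wall rectangle; ``trim_wall_px`` wall pixels are removed from the
    outer corner so total areas can hit arbitrary pixel counts exactly.
    """
    oh, ow = outer_px
    lh, lw = lumen_px
    h, w = oh + 8, ow + 8
    labels = np.zeros((h, w), dtype=np.uint8)
    r0, c0 = 4, 4
    labels[r0 : r0 + oh, c0 : c0 + ow] = 2
    lr = r0 + (oh - lh) // 2
    lc = c0 + (ow - lw) // 2
    labels[lr : lr + lh, lc : lc + lw] = 1
    if trim_wall_px:
        wall_coords = np.argwhere(labels == 2)
        for y, x in wall_coords[:trim_wall_px]:
            labels[y, x] = 0
    return SegmentedVessel(
        vessel_id=vessel_id,
        labels=labels,
        calibration=PixelCalibration(microns_per_pixel),
        **flags,
    )
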