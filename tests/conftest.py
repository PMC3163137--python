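import dataclasses

import numpy as np
import pytest
from hypothesis import settings

import lymphquant as lq

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None, database=None)
settings.load_profile("ci")

#: Small slide configuration used by most pipeline tests: same palette and
#: proportions as the default validation slide, at a quarter of the side.
SMALL_CONFIG = lq.SynthConfig(
    image_size_px=(800, 800),
    n_vessels=15,
    vessel_radius_um=(10.0, 25.0),
    tumor_radius_um=(60.0, 90.0),
    seed=0,
)


def small_config(**overrides) -> lq.SynthConfig:
    return dataclasses.replace(SMALL_CONFIG, **overrides)


@pytest.fixture(scope="session")
def small_slide():
    """One small synthetic slide with ground truth (seed 0)."""
    return lq.generate_slide(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_segmentation(small_slide):
    image, _ = small_slide
    return lq.segment_slide(image)


def make_record(
    distance_mm: float,
    angle_deg: float = 0.0,
    label: int = 1,
    centroid_rc: tuple[float, float] = (0.0, 0.0),
) -> lq.VesselRecord:
    """VesselRecord with only the fields a spatial statistic needs."""
    return lq.VesselRecord(
        label=label,
        centroid_rc=centroid_rc,
        area_px=1,
        area_um2=1.0,
        distance_to_tumor_mm=distance_mm,
        angle_deg=angle_deg,
    )
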