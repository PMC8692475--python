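import numpy as np
import pytest

from srusval.geometry import RasterGeometry
from srusval.phantom import (FlowSense, KidneyPhantom, PhantomConfig, Side,
                             SlabGeometry, VesselClass, VesselSegment,
                             generate_kidney_phantom)


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    return PhantomConfig(n_segmental=3, n_arcuate=4, n_cortical_radial=4,
                         n_vasa_recta_bundles=1, bundle_size=4)


@pytest.fixture(scope="session")
def small_phantom(small_config) -> KidneyPhantom:
    return generate_kidney_phantom(small_config, seed=7)


@pytest.fixture()
def grid() -> RasterGeometry:
    return RasterGeometry(shape=(100, 120), pixel_size=0.1)


@pytest.fixture()
def slab() -> SlabGeometry:
    return SlabGeometry(in_plane_extent=(10.0, 12.0), elevation_thickness=1.8)


def straight_pair_phantom(length: float = 10.0, radius: float = 0.02,
                          speed: float = 5.4, pulsatility: float = 0.0,
                          vein_offset: float = 1.0) -> KidneyPhantom:
    """Minimal phantom: one straight artery with its paired parallel vein."""
    n = max(int(length / 0.5) + 1, 2)
    ys = np.linspace(0.5, 0.5 + length, n)
    art_poly = np.stack([np.full(n, 5.0), ys, np.zeros(n)], axis=1)
    artery = VesselSegment(id=0, parent_id=None, polyline=art_poly, radius=radius,
                           vessel_class=VesselClass.segmental, side=Side.artery,
                           mean_speed=speed, pulsatility=pulsatility,
                           flow_sense=FlowSense.antegrade, pair_id=1)
    vein = VesselSegment(id=1, parent_id=None,
                         polyline=art_poly + np.array([vein_offset, 0.0, 0.0]),
                         radius=radius * 1.6, vessel_class=VesselClass.segmental,
                         side=Side.vein, mean_speed=speed * 0.6, pulsatility=0.0,
                         flow_sense=FlowSense.retrograde, pair_id=0)
    extent = ((0.0, 10.0), (0.0, length + 1.0), (-1.0, 1.0))
    return KidneyPhantom(segments=[artery, vein], extent=extent, seed=0)
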