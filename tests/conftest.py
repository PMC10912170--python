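import sys
from pathlib import Path

import numpy as np
import pytest
import trimesh

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from perisoma.simulate import TissueConfig, simulate_volume
from perisoma.surfaces import CellSurface


def pair_config(seed: int, coverage: float = 0.3, **overrides) -> TissueConfig:
    """A small single-pair specimen (one neuron, one apposed microglia)."""
    kwargs = dict(
        volume_shape=(44, 112, 112),
        n_neurons=1,
        n_microglia=1,
        p_assoc=1.0,
        coverage_assoc=coverage,
        coverage_nonassoc=min(0.02, coverage / 2),
        neuron_radius_um=(4.2, 0.2),
        microglia_radius_um=(4.2, 0.2),
        seed=seed,
    )
    kwargs.update(overrides)
    return TissueConfig(**kwargs)


@pytest.fixture(scope="session")
def demo_specimen():
    """A small multi-cell specimen shared by read-only tests."""
    cfg = TissueConfig(volume_shape=(48, 150, 150), n_neurons=2, n_microglia=2, seed=7)
    return cfg, *simulate_volume(cfg)


def icosphere_surface(radius: float, center, cell_id: int = 1, cell_class: str = "neuron_soma",
                      subdivisions: int = 3) -> CellSurface:
    """An analytic sphere wrapped as a CellSurface (no voxel provenance)."""
    mesh = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    mesh.apply_translation(np.asarray(center, dtype=float))
    return CellSurface(
        cell_id=cell_id,
        cell_class=cell_class,
        mesh=mesh,
        centroid=np.asarray(center, dtype=float),
        area=float(mesh.area),
        volume=float(mesh.volume),
    )
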