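import numpy as np
import pandas as pd
import pytest

from dentaccess import (
    MatrixTravelTimeProvider,
    RegionSpec,
    SpatialWeights,
    generate_region,
    simulate_travel_times,
)
from dentaccess.region import _lattice_rook_edges


def lattice_weights(rows: int, cols: int, style: str = "row-standardized") -> SpatialWeights:
    """Rook weights of a rows x cols lattice with integer ids 0..n-1."""
    return SpatialWeights.from_edges(
        _lattice_rook_edges(rows, cols), ids=list(range(rows * cols)), style=style
    )


def random_instance(n_villages: int, n_facilities: int, seed: int, box_km: float = 30.0):
    """Small random village/facility tables plus a noisy symmetric provider."""
    rng = np.random.default_rng(seed)
    villages = pd.DataFrame(
        {
            "village_id": [f"V{i}" for i in range(n_villages)],
            "x": rng.uniform(0, box_km * 1000, n_villages),
            "y": rng.uniform(0, box_km * 1000, n_villages),
            "population": rng.integers(100, 10_000, n_villages),
            "township_id": rng.choice(["T0", "T1", "T2"], n_villages),
            "county_id": "C0",
        }
    )
    facilities = pd.DataFrame(
        {
            "facility_id": [f"F{j}" for j in range(n_facilities)],
            "x": rng.uniform(0, box_km * 1000, n_facilities),
            "y": rng.uniform(0, box_km * 1000, n_facilities),
            "dentists": rng.integers(1, 6, n_facilities),
        }
    )
    od = simulate_travel_times(villages, facilities, seed=seed + 1)
    provider = MatrixTravelTimeProvider(od.to_numpy(), list(od.index), list(od.columns))
    return villages, facilities, provider


@pytest.fixture(scope="session")
def small_region():
    """A compact synthetic region shared across read-only tests."""
    spec = RegionSpec(
        grid_shape=(4, 4),
        villages_per_township=(3, 6),
        n_facilities=40,
        seed=20,
    )
    return generate_region(spec)
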