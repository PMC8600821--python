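"""Synthetic study regions for the accessibility-and-quality analysis.

A region is a rectangular lattice of square townships (planar coordinates,
metres — no geodesy).  Each township holds villages with log-normal
populations placed uniformly inside its cell; dental facilities sit at
village centroids, drawn with probability proportional to
population^facility_pop_bias so supply clusters toward dense areas, as it
does in real regions.  Rook adjacency of the lattice cells gives the
township contiguity structure, and a 7-level urbanization gradient (highly
urban .. remote township) is assigned by population-density septiles.

Quality indexes are generated by the spatial-error process the downstream
regression assumes: y = X beta + u with u = (I - lambda W)^{-1} eps, so
that estimator-recovery tests have a known ground truth.

All randomness flows from a single master seed through independent
spawned streams (placement, populations, facilities, noise), so adding one
generator never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .weights import SpatialWeights

__all__ = [
    "URBANIZATION_LEVELS",
    "RegionSpec",
    "QualitySimSpec",
    "SyntheticRegion",
    "generate_region",
    "simulate_travel_times",
    "simulate_quality_panel",
    "write_region",
    "write_od_long",
]

# ordered most to least urban
URBANIZATION_LEVELS = (
    "highly urban",
    "moderately urban",
    "emerging",
    "general",
    "aging",
    "agriculture",
    "remote",
)


@dataclass(frozen=True)
class RegionSpec:
    """Parameters of the synthetic region generator.

    Defaults emulate the scale of the Taiwanese study area: a 360-township
    lattice (~7,500 villages in total), village populations log-normal with
    a spatially correlated township density gradient (urban cores vs remote
    peripheries), ~6,900 dental facilities holding ~15,000 dentists (about
    one dentist per 1,500 persons) clustered toward populous villages,
    10 km township cells and a 60 km/h travel speed.
    """

    grid_shape: tuple[int, int] = (18, 20)
    villages_per_township: int | tuple[int, int] = (12, 30)
    pop_lognormal_params: tuple[float, float] = (7.5, 1.0)
    density_gradient_sd: float = 0.6
    density_gradient_rho: float = 0.7
    n_facilities: int = 6900
    facility_pop_bias: float = 1.4
    speed_kmh: float = 60.0
    cell_size_m: float = 10_000.0
    urbanization_levels: tuple[str, ...] = URBANIZATION_LEVELS
    seed: int = 0

    @property
    def n_townships(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def __post_init__(self) -> None:
        rows, cols = self.grid_shape
        if rows < 1 or cols < 1:
            raise ValueError(f"grid_shape must be >= (1, 1), got {self.grid_shape}")
        vpt = self.villages_per_township
        lo, hi = (vpt, vpt) if isinstance(vpt, int) else vpt
        if lo < 1 or hi < lo:
            raise ValueError(f"villages_per_township invalid: {vpt}")
        mu, sigma = self.pop_lognormal_params
        if sigma < 0:
            raise ValueError(f"pop_lognormal_params sigma must be >= 0, got {sigma}")
        if self.density_gradient_sd < 0:
            raise ValueError(
                f"density_gradient_sd must be >= 0, got {self.density_gradient_sd}"
            )
        if not (0 <= self.density_gradient_rho < 1):
            raise ValueError(
                f"density_gradient_rho must be in [0, 1), got {self.density_gradient_rho}"
            )
        if self.n_facilities < 1:
            raise ValueError(f"n_facilities must be >= 1, got {self.n_facilities}")
        if self.facility_pop_bias < 0:
            raise ValueError(
                f"facility_pop_bias must be >= 0, got {self.facility_pop_bias}"
            )
        if self.speed_kmh <= 0:
            raise ValueError(f"speed_kmh must be > 0, got {self.speed_kmh}")
        if self.cell_size_m <= 0:
            raise ValueError(f"cell_size_m must be > 0, got {self.cell_size_m}")
        if len(self.urbanization_levels) < 1:
            raise ValueError("urbanization_levels must be non-empty")


@dataclass(frozen=True)
class QualitySimSpec:
    """Generative spatial-error process for a quality index.

    ``beta`` is (intercept, accessibility effect, DMFT effect) unless a
    different design is supplied; ``lam`` must lie strictly inside the
    admissible interval (1/w_min, 1/w_max) of the weights' eigenvalues.
    """

    beta: tuple[float, ...]
    lam: float = 0.0
    sigma_eps: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        # sigma_eps = 0 is allowed as the exact noiseless limit y = X beta
        if self.sigma_eps < 0:
            raise ValueError(f"sigma_eps must be >= 0, got {self.sigma_eps}")


@dataclass(frozen=True)
class SyntheticRegion:
    """Bundle of generated tables (all plain pandas DataFrames)."""

    villages: pd.DataFrame      # village_id, x, y, population, township_id, county_id
    facilities: pd.DataFrame    # facility_id, x, y, dentists, village_id
    townships: pd.DataFrame     # township_id, row, col, population, density_per_km2,
                                # urbanization, county_id
    adjacency: pd.DataFrame     # township_a, township_b (rook lattice edges)
    urbanization: dict = field(repr=False)
    metadata: dict = field(repr=False)

    def weights(self, style: str = "row-standardized") -> SpatialWeights:
        edges = list(self.adjacency.itertuples(index=False, name=None))
        return SpatialWeights.from_edges(
            edges, ids=self.townships["township_id"].tolist(), style=style
        )


def _lattice_rook_edges(rows: int, cols: int) -> list[tuple[int, int]]:
    edges = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                edges.append((i, i + 1))
            if r + 1 < rows:
                edges.append((i, i + cols))
    return edges


def generate_region(spec: RegionSpec) -> SyntheticRegion:
    """Draw a full synthetic region from ``spec`` (deterministic in seed)."""
    rows, cols = spec.grid_shape
    ss = np.random.SeedSequence(spec.seed)
    rng_place, rng_pop, rng_fac, _ = (np.random.default_rng(s) for s in ss.spawn(4))

    vpt = spec.villages_per_township
    lo, hi = (vpt, vpt) if isinstance(vpt, int) else vpt
    n_town = spec.n_townships
    counts = rng_place.integers(lo, hi + 1, size=n_town)

    town_ids = [f"T{i:04d}" for i in range(n_town)]
    town_rows = np.repeat(np.arange(rows), cols)
    town_cols = np.tile(np.arange(cols), rows)
    county_ids = [f"C{r:02d}" for r in town_rows]

    vids, vx, vy, vtown, vcounty = [], [], [], [], []
    k = 0
    for t in range(n_town):
        r, c = town_rows[t], town_cols[t]
        n_v = int(counts[t])
        xs = (c + rng_place.random(n_v)) * spec.cell_size_m
        ys = (r + rng_place.random(n_v)) * spec.cell_size_m
        for x, y in zip(xs, ys):
            vids.append(f"V{k:05d}")
            vx.append(x)
            vy.append(y)
            vtown.append(town_ids[t])
            vcounty.append(county_ids[t])
            k += 1

    # spatially correlated township density field: urban cores and remote
    # peripheries emerge as contiguous blocks rather than salt-and-pepper
    offsets = np.zeros(n_town)
    if spec.density_gradient_sd > 0 and n_town > 1:
        eps = rng_pop.normal(size=n_town)
        A = np.zeros((n_town, n_town))
        for a, b in _lattice_rook_edges(rows, cols):
            A[a, b] = A[b, a] = 1.0
        Wm = A / A.sum(axis=1, keepdims=True)
        u = np.linalg.solve(
            np.eye(n_town) - spec.density_gradient_rho * Wm, eps
        )
        u_sd = u.std()
        if u_sd > 0:
            offsets = (u - u.mean()) / u_sd * spec.density_gradient_sd

    mu, sigma = spec.pop_lognormal_params
    town_pos = {t: i for i, t in enumerate(town_ids)}
    mu_village = mu + np.array([offsets[town_pos[t]] for t in vtown])
    pops = np.maximum(
        1, np.round(rng_pop.lognormal(mu_village, sigma, size=k))
    ).astype(int)

    villages = pd.DataFrame(
        {
            "village_id": vids,
            "x": vx,
            "y": vy,
            "population": pops,
            "township_id": vtown,
            "county_id": vcounty,
        }
    )

    # facility placement: probability proportional to population^bias
    weights_raw = pops.astype(float) ** spec.facility_pop_bias
    probs = weights_raw / weights_raw.sum()
    host = rng_fac.choice(k, size=spec.n_facilities, replace=True, p=probs)
    dentists = 1 + rng_fac.poisson(1.2, size=spec.n_facilities)
    # clinics sit near, not exactly on, the village centroid: 50-300 m
    # offset so travel times between distinct points are strictly positive
    theta = rng_fac.uniform(0, 2 * np.pi, size=spec.n_facilities)
    radius = rng_fac.uniform(50.0, 300.0, size=spec.n_facilities)
    facilities = pd.DataFrame(
        {
            "facility_id": [f"F{j:04d}" for j in range(spec.n_facilities)],
            "x": villages["x"].to_numpy()[host] + radius * np.cos(theta),
            "y": villages["y"].to_numpy()[host] + radius * np.sin(theta),
            "dentists": dentists,
            "village_id": villages["village_id"].to_numpy()[host],
        }
    )

    town_pop = villages.groupby("township_id", sort=True)["population"].sum()
    cell_km2 = (spec.cell_size_m / 1000.0) ** 2
    density = town_pop.reindex(town_ids).fillna(0).to_numpy() / cell_km2
    urb = _density_septiles(density, spec.urbanization_levels)

    townships = pd.DataFrame(
        {
            "township_id": town_ids,
            "row": town_rows,
            "col": town_cols,
            "population": town_pop.reindex(town_ids).fillna(0).astype(int).to_numpy(),
            "density_per_km2": density,
            "urbanization": urb,
            "county_id": county_ids,
        }
    )

    edges = _lattice_rook_edges(rows, cols)
    adjacency = pd.DataFrame(
        [(town_ids[a], town_ids[b]) for a, b in edges],
        columns=["township_a", "township_b"],
    )

    metadata = {
        "seed": spec.seed,
        "grid_shape": list(spec.grid_shape),
        "n_townships": n_town,
        "n_villages": int(k),
        "n_facilities": int(spec.n_facilities),
        "total_population": int(pops.sum()),
        "total_dentists": int(dentists.sum()),
        "cell_size_m": spec.cell_size_m,
        "speed_kmh": spec.speed_kmh,
    }
    return SyntheticRegion(
        villages=villages,
        facilities=facilities,
        townships=townships,
        adjacency=adjacency,
        urbanization=dict(zip(town_ids, urb)),
        metadata=metadata,
    )


def _density_septiles(density: np.ndarray, levels: tuple[str, ...]) -> list[str]:
    """Ordered labels by density rank: densest block gets the most urban label."""
    n = len(density)
    g = len(levels)
    # rank densest first; stable so ties break by township order
    order = np.argsort(-density, kind="stable")
    labels = np.empty(n, dtype=object)
    blocks = np.array_split(order, g)
    for lab, blk in zip(levels, blocks):
        labels[blk] = lab
    return list(labels)


def simulate_travel_times(
    villages: pd.DataFrame,
    facilities: pd.DataFrame,
    speed_kmh: float = 60.0,
    noise_factor_range: tuple[float, float] = (1.0, 1.4),
    seed: int | None = None,
) -> pd.DataFrame:
    """Origin-destination minutes: Euclidean distance / speed times a road
    detour factor drawn uniformly per (village, facility) pair.

    The factor is attached to the unordered pair, so time(i, j) = time(j, i)
    by construction.  Returns a (n_villages, n_facilities) DataFrame indexed
    by village_id with facility_id columns.
    """
    if speed_kmh <= 0:
        raise ValueError("speed_kmh must be > 0")
    lo, hi = noise_factor_range
    if lo < 1 or hi < lo:
        raise ValueError(f"noise factors must satisfy 1 <= lo <= hi, got {noise_factor_range}")
    vc = villages[["x", "y"]].to_numpy(dtype=float)
    fc = facilities[["x", "y"]].to_numpy(dtype=float)
    d = np.hypot(vc[:, None, 0] - fc[None, :, 0], vc[:, None, 1] - fc[None, :, 1])
    rng = np.random.default_rng(seed)
    factor = rng.uniform(lo, hi, size=d.shape)
    minutes = d / 1000.0 / speed_kmh * 60.0 * factor
    minutes[d == 0] = 0.0  # zero distance is zero time regardless of factor
    return pd.DataFrame(
        minutes,
        index=pd.Index(villages["village_id"], name="origin_id"),
        columns=pd.Index(facilities["facility_id"], name="dest_id"),
    )


def simulate_quality_panel(
    townships: pd.DataFrame,
    w: SpatialWeights,
    X: pd.DataFrame,
    spec: QualitySimSpec,
) -> tuple[pd.Series, pd.Series]:
    """One cross-section of a quality index under the spatial-error process.

    y = X beta + u with u = (I - lambda W)^{-1} eps, eps ~ N(0, sigma_eps^2).
    ``X`` rows must align with ``w.ids``; a leading intercept column is
    expected if beta includes one.  Returns ``(y, u)`` so tests can check
    the realized error field directly.
    """
    w = w.row_standardized()
    ids = list(w.ids)
    if list(X.index) != ids:
        X = X.loc[ids]
    Xm = X.to_numpy(dtype=float)
    beta = np.asarray(spec.beta, dtype=float)
    if Xm.shape[1] != beta.size:
        raise ValueError(
            f"X has {Xm.shape[1]} columns but beta has {beta.size} entries"
        )
    from .sem import _weights_eigenvalues

    omega = _weights_eigenvalues(w)
    lam_lo, lam_hi = 1.0 / float(omega.min()), 1.0 / float(omega.max())
    if not (lam_lo < spec.lam < lam_hi):
        raise ValueError(
            f"lambda={spec.lam} outside admissible interval ({lam_lo:.4g}, {lam_hi:.4g})"
        )
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, spec.sigma_eps, size=len(ids))
    B = np.eye(len(ids)) - spec.lam * w.sparse().toarray()
    u = np.linalg.solve(B, eps)
    y = Xm @ beta + u
    return (
        pd.Series(y, index=pd.Index(ids, name="township_id"), name="y"),
        pd.Series(u, index=pd.Index(ids, name="township_id"), name="u"),
    )


# -- serialization ---------------------------------------------------------


def _cell_polygon(row: int, col: int, cell: float) -> list[list[list[float]]]:
    x0, y0 = col * cell, row * cell
    x1, y1 = x0 + cell, y0 + cell
    return [[[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]]]


def region_geojson(region: SyntheticRegion, cell_size_m: float | None = None) -> dict:
    """Township cells as a GeoJSON FeatureCollection (planar coordinates)."""
    cell = cell_size_m or float(region.metadata["cell_size_m"])
    feats = []
    for rec in region.townships.itertuples(index=False):
        feats.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": _cell_polygon(int(rec.row), int(rec.col), cell),
                },
                "properties": {
                    "township_id": rec.township_id,
                    "population": int(rec.population),
                    "urbanization": rec.urbanization,
                    "county_id": rec.county_id,
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}


def write_region(region: SyntheticRegion, outdir: str | Path) -> None:
    """Write villages/facilities/townships CSV, adjacency CSV, cells GeoJSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    region.villages.to_csv(outdir / "villages.csv", index=False)
    region.facilities.to_csv(outdir / "facilities.csv", index=False)
    region.townships.to_csv(outdir / "townships.csv", index=False)
    region.adjacency.to_csv(outdir / "adjacency.csv", index=False)
    with open(outdir / "townships.geojson", "w") as fh:
        json.dump(region_geojson(region), fh, sort_keys=True)
    with open(outdir / "region_metadata.json", "w") as fh:
        json.dump(region.metadata, fh, indent=2, sort_keys=True)


def write_od_long(od: pd.DataFrame, path: str | Path) -> None:
    """OD matrix to long-format CSV (origin_id, dest_id, minutes)."""
    long = od.stack().rename("minutes").reset_index()
    long.to_csv(path, index=False)
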