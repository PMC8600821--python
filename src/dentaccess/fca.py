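"""Two-step floating catchment area (2SFCA) accessibility scoring.

Demand is a table of villages (centroid, population); supply is a table of
dental facilities (location, dentist count).  Step 1 computes each
facility's supply-to-demand ratio over the population inside its travel-time
catchment (10 minutes by default, closed boundary).  Step 2 sums, for each
village, the ratios of every facility reachable within the same threshold;
that sum is the village's accessibility score R — the annual per-person
supply of dentist services.

Scores convert to the familiar provider-to-population language through
``provider_ratio_to_threshold``: one dentist per 2000 people corresponds to
R = 0.0005, and the 1:4000 shortage criterion to R = 0.00025. Townships with
population-weighted mean R below a threshold are flagged dental-resource
deficient.

Tables of villages must carry columns ``village_id, x, y, population,
township_id`` (``county_id`` optional); facilities carry ``facility_id, x,
y, dentists``. Coordinates are planar metres.
"""

from __future__ import annotations

import logging
from typing import Mapping, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

__all__ = [
    "TravelTimeProvider",
    "MatrixTravelTimeProvider",
    "EuclideanTravelTimeProvider",
    "build_catchments",
    "step1_supply_demand_ratios",
    "step2_accessibility",
    "accessibility_scores",
    "provider_ratio_to_threshold",
    "classify_deficiency",
    "quartile_grouping",
]

logger = logging.getLogger(__name__)

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")
ZERO_GROUP = "zero"


@runtime_checkable
class TravelTimeProvider(Protocol):
    """Travel time lookup between village and facility ids, in minutes.

    Implementations must be non-negative with time(a, a) = 0, and symmetric
    unless ``asymmetric`` is True.
    """

    asymmetric: bool

    def time(self, village_id, facility_id) -> float: ...

    def matrix(self, village_ids: Sequence, facility_ids: Sequence) -> np.ndarray:
        """(n_villages, n_facilities) minute matrix; default loops ``time``."""
        ...


class MatrixTravelTimeProvider:
    """Travel times served from a precomputed village x facility matrix."""

    asymmetric = False

    def __init__(self, minutes: np.ndarray, village_ids: Sequence, facility_ids: Sequence):
        minutes = np.asarray(minutes, dtype=float)
        if minutes.shape != (len(village_ids), len(facility_ids)):
            raise ValueError("matrix shape does not match id lists")
        if (minutes < 0).any():
            raise ValueError("negative travel time in matrix")
        self._m = minutes
        self._vidx = {v: i for i, v in enumerate(village_ids)}
        self._fidx = {f: j for j, f in enumerate(facility_ids)}

    @classmethod
    def from_long_frame(cls, od: pd.DataFrame) -> "MatrixTravelTimeProvider":
        """Build from long format with columns origin_id, dest_id, minutes."""
        wide = od.pivot(index="origin_id", columns="dest_id", values="minutes")
        if wide.isna().any().any():
            raise ValueError("OD table is not a complete village x facility grid")
        return cls(wide.to_numpy(), list(wide.index), list(wide.columns))

    def time(self, village_id, facility_id) -> float:
        return float(self._m[self._vidx[village_id], self._fidx[facility_id]])

    def matrix(self, village_ids, facility_ids) -> np.ndarray:
        vi = [self._vidx[v] for v in village_ids]
        fi = [self._fidx[f] for f in facility_ids]
        return self._m[np.ix_(vi, fi)]


class EuclideanTravelTimeProvider:
    """Straight-line drive time at a constant speed (default 60 km/h)."""

    asymmetric = False

    def __init__(self, villages: pd.DataFrame, facilities: pd.DataFrame,
                 speed_kmh: float = 60.0):
        if speed_kmh <= 0:
            raise ValueError("speed_kmh must be > 0")
        self._v = villages.set_index("village_id")[["x", "y"]]
        self._f = facilities.set_index("facility_id")[["x", "y"]]
        self.speed_kmh = speed_kmh

    def time(self, village_id, facility_id) -> float:
        dx = self._v.loc[village_id] - self._f.loc[facility_id].to_numpy()
        dist_m = float(np.hypot(dx.iloc[0], dx.iloc[1]))
        return dist_m / 1000.0 / self.speed_kmh * 60.0

    def matrix(self, village_ids, facility_ids) -> np.ndarray:
        vc = self._v.loc[list(village_ids)].to_numpy()
        fc = self._f.loc[list(facility_ids)].to_numpy()
        d = np.hypot(vc[:, None, 0] - fc[None, :, 0], vc[:, None, 1] - fc[None, :, 1])
        return d / 1000.0 / self.speed_kmh * 60.0


def _time_matrix(villages, facilities, provider) -> np.ndarray:
    vids = villages["village_id"].tolist()
    fids = facilities["facility_id"].tolist()
    if hasattr(provider, "matrix"):
        m = np.asarray(provider.matrix(vids, fids), dtype=float)
    else:
        m = np.array([[provider.time(v, f) for f in fids] for v in vids], dtype=float)
    if (m < 0).any():
        raise ValueError("travel-time provider returned a negative time")
    return m


def build_catchments(
    facilities: pd.DataFrame,
    villages: pd.DataFrame,
    provider: TravelTimeProvider,
    t0: float = 10.0,
) -> dict:
    """Map each facility to the set of village ids within ``t0`` minutes.

    Membership is computed from the village centroid to the facility, with a
    closed boundary: a village exactly at the threshold is included.
    """
    if t0 <= 0:
        raise ValueError("t0 must be > 0")
    m = _time_matrix(villages, facilities, provider)
    vids = villages["village_id"].to_numpy()
    out = {}
    for j, fid in enumerate(facilities["facility_id"]):
        out[fid] = set(vids[m[:, j] <= t0])
    return out


def step1_supply_demand_ratios(
    catchments: Mapping, villages: pd.DataFrame, facilities: pd.DataFrame
) -> pd.Series:
    """Facility supply-to-demand ratios R_j = S_j / sum of catchment population.

    A facility whose catchment is empty (or has zero population) gets
    R_j = 0 with a warning; it then simply contributes nothing in step 2.
    """
    pop = villages.set_index("village_id")["population"]
    ratios = {}
    for fid, supply in facilities.set_index("facility_id")["dentists"].items():
        if supply <= 0:
            raise ValueError(f"facility {fid!r} has non-positive supply")
        members = catchments.get(fid, set())
        demand = float(pop.loc[list(members)].sum()) if members else 0.0
        if demand <= 0:
            logger.warning(
                "facility %s has an empty or zero-population catchment; R_j = 0",
                fid,
            )
            ratios[fid] = 0.0
        else:
            ratios[fid] = float(supply) / demand
    return pd.Series(ratios, name="ratio").rename_axis("facility_id")


def step2_accessibility(
    villages: pd.DataFrame,
    facilities: pd.DataFrame,
    provider: TravelTimeProvider,
    t0: float,
    ratios: pd.Series,
) -> pd.DataFrame:
    """Village accessibility R_i = sum of ratios of facilities within t0.

    Returns a frame with columns ``village_id, R``; villages reached by no
    facility get R = 0.
    """
    m = _time_matrix(villages, facilities, provider)
    r = ratios.loc[facilities["facility_id"]].to_numpy()
    reach = m <= t0
    scores = reach @ r
    return pd.DataFrame({"village_id": villages["village_id"], "R": scores})


def accessibility_scores(
    villages: pd.DataFrame,
    facilities: pd.DataFrame,
    provider: TravelTimeProvider,
    t0: float = 10.0,
) -> pd.DataFrame:
    """Both 2SFCA steps in sequence with a single threshold and provider."""
    catch = build_catchments(facilities, villages, provider, t0)
    ratios = step1_supply_demand_ratios(catch, villages, facilities)
    return step2_accessibility(villages, facilities, provider, t0, ratios)


def provider_ratio_to_threshold(persons_per_dentist: float) -> float:
    """Convert a persons-per-dentist ratio to an accessibility threshold.

    1:2000 -> 0.0005 service trips per person per year; 1:4000 -> 0.00025.
    """
    if persons_per_dentist <= 0:
        raise ValueError("persons_per_dentist must be > 0")
    return 1.0 / persons_per_dentist


def classify_deficiency(
    table: pd.DataFrame,
    villages: pd.DataFrame,
    thresholds: Sequence[float] = (0.0005, 0.00025),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag dental-resource-deficient townships.

    Village scores aggregate to the township level by the
    population-weighted mean of R; a township is deficient under a threshold
    when its aggregate falls strictly below it.

    Returns ``(township_table, summary)``: the per-township aggregate with
    one boolean column per threshold, and a summary frame with the count and
    percentage of deficient townships per threshold.
    """
    for t in thresholds:
        if t <= 0:
            raise ValueError("thresholds must be > 0")
    df = table.merge(villages[["village_id", "population", "township_id"]],
                     on="village_id", validate="one_to_one")

    def _wmean(g: pd.DataFrame) -> float:
        w = g["population"].to_numpy(dtype=float)
        if w.sum() == 0:
            return float(g["R"].mean())
        return float(np.average(g["R"], weights=w))

    agg = (
        df.groupby("township_id", sort=True)
        .apply(_wmean, include_groups=False)
        .rename("R_township")
        .reset_index()
    )
    rows = []
    for t in thresholds:
        col = f"deficient_{t:g}"
        agg[col] = agg["R_township"] < t
        n_def = int(agg[col].sum())
        rows.append(
            {
                "threshold": t,
                "n_deficient": n_def,
                "n_townships": len(agg),
                "pct_deficient": percentage(n_def, len(agg)),
            }
        )
    return agg, pd.DataFrame(rows)


def percentage(part: float, whole: float, decimals: int = 2) -> float:
    """Share of ``whole`` in percent, rounded for reporting (two decimals)."""
    if whole == 0:
        raise ValueError("percentage of an empty total is undefined")
    return round(100.0 * part / whole, decimals)


def quartile_grouping(table: pd.DataFrame) -> pd.DataFrame:
    """Assign the five-group accessibility classification.

    Villages with R = 0 form the "zero" group; quartile cut points are the
    unweighted quantiles of the R > 0 subset, with half-open (low, cut]
    bins.  If the positive scores are so tied that the cut points collapse,
    groups are assigned by stable rank order into four near-equal blocks
    (with a warning).
    """
    out = table.copy()
    pos_mask = out["R"] > 0
    pos = out.loc[pos_mask, "R"]
    if len(pos) < 4:
        raise ValueError(f"need at least 4 villages with R > 0, got {len(pos)}")
    cuts = np.quantile(pos.to_numpy(), [0.25, 0.5, 0.75])
    group = np.full(len(out), ZERO_GROUP, dtype=object)
    if np.unique(cuts).size < 3:
        logger.warning("degenerate quartile cut points; assigning by stable order")
        order = np.argsort(pos.to_numpy(), kind="stable")
        blocks = np.array_split(order, 4)
        labels = np.empty(len(pos), dtype=object)
        for lab, blk in zip(QUARTILE_LABELS, blocks):
            labels[blk] = lab
        group[np.flatnonzero(pos_mask.to_numpy())] = labels
    else:
        # side="left": R equal to a cut point stays in the lower bin
        idx = np.searchsorted(cuts, pos.to_numpy(), side="left")
        group[np.flatnonzero(pos_mask.to_numpy())] = np.array(QUARTILE_LABELS)[idx]
    out["quartile_group"] = group
    return out
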