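"""Supporting spatial statistics.

Zone-level elderly population density, Clark–Evans average nearest
neighbor (ANN) clustering of facility locations, quantile classification
of accessibility scores into discrete levels, and side-by-side summary
statistics for model-variant comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Hashable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .accessibility import AccessibilityResult

__all__ = [
    "ZoneSummary",
    "AnnReport",
    "density",
    "average_nearest_neighbor",
    "classify_levels",
    "compare_variants",
]

#: Clark–Evans standard-error constant, as used by the standard GIS tool.
ANN_SE_CONSTANT = 0.26136


@dataclass(frozen=True)
class ZoneSummary:
    """One reporting zone: elderly population, area and density."""

    id: Hashable
    population: float
    area_km2: float
    density: float  # persons / km^2


@dataclass(frozen=True)
class AnnReport:
    """Average nearest neighbor analysis of a point pattern.

    ``ann < 1`` indicates clustering, ``> 1`` dispersion; ``z`` is the
    Clark–Evans standardized score of the observed mean nearest-neighbor
    distance against complete spatial randomness.
    """

    n: int
    study_area_m2: float
    observed_mean_nn_m: float
    expected_mean_nn_m: float
    ann: float
    z: float

    def to_dict(self) -> Dict[str, float]:
        return {
            "n": self.n,
            "study_area_m2": self.study_area_m2,
            "observed_mean_nn_m": self.observed_mean_nn_m,
            "expected_mean_nn_m": self.expected_mean_nn_m,
            "ann": self.ann,
            "z": self.z,
        }


def density(zones: Sequence[Tuple[Hashable, float, float]]) -> List[ZoneSummary]:
    """Elderly population density per zone.

    ``zones`` is a sequence of ``(id, population, area_km2)``; the output is
    sorted by id.  Nonpositive areas are an error naming the zone.
    """
    out: List[ZoneSummary] = []
    for zid, pop, area in zones:
        if not (area > 0 and math.isfinite(area)):
            raise ValueError(f"zone {zid}: area must be positive, got {area}")
        if not (pop >= 0 and math.isfinite(pop)):
            raise ValueError(f"zone {zid}: population must be nonnegative, got {pop}")
        out.append(ZoneSummary(id=zid, population=pop, area_km2=area, density=pop / area))
    return sorted(out, key=lambda z: str(z.id))


def average_nearest_neighbor(
    points: Sequence[Tuple[float, float]], study_area_m2: float
) -> AnnReport:
    """Clark–Evans average nearest neighbor index and z-score.

    observed = mean distance from each point to its nearest other point;
    expected (under complete spatial randomness) = ``0.5 / sqrt(n / A)``;
    ``ann = observed / expected``;
    ``z = (observed - expected) / (0.26136 / sqrt(n^2 / A))``.

    Duplicate points are allowed (their nearest-neighbor distance is 0).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n < 2:
        raise ValueError("average nearest neighbor requires at least 2 points")
    if not study_area_m2 > 0:
        raise ValueError("study area must be positive")
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=2)
    observed = float(dist[:, 1].mean())
    expected = 0.5 / math.sqrt(n / study_area_m2)
    se = ANN_SE_CONSTANT / math.sqrt(n * n / study_area_m2)
    return AnnReport(
        n=n,
        study_area_m2=float(study_area_m2),
        observed_mean_nn_m=observed,
        expected_mean_nn_m=expected,
        ann=observed / expected,
        z=(observed - expected) / se,
    )


def classify_levels(values: Mapping[Hashable, float], k: int = 10) -> Dict[Hashable, int]:
    """Quantile classification of scores into ``k`` levels (1 = lowest).

    Level boundaries sit at the ``i/k`` empirical quantiles; a value equal
    to a boundary is assigned to the lower level, so ties share a level and
    an all-equal input maps everything to level 1.  Classification is
    monotone: ``v1 <= v2`` implies ``level(v1) <= level(v2)``.
    """
    if k < 2:
        raise ValueError("need at least 2 levels")
    if not values:
        raise ValueError("no values to classify")
    arr = np.array(list(values.values()), dtype=float)
    bounds = np.quantile(arr, [i / k for i in range(1, k)])
    return {key: 1 + int(np.sum(v > bounds)) for key, v in values.items()}


def compare_variants(results: Sequence[AccessibilityResult]) -> pd.DataFrame:
    """Summary statistics of A_i per model variant, one row per result.

    Columns: ``variant, mean, min, max, sd`` — the standard deviation uses
    the population (n) denominator, appropriate for a full enumeration of
    reporting zones rather than a sample.  All results must cover the same
    demand set.
    """
    if not results:
        raise ValueError("no results to compare")
    base_ids = set(results[0].access)
    rows = []
    for res in results:
        if set(res.access) != base_ids:
            raise ValueError("results computed on different demand sets cannot be compared")
        a = np.array(list(res.access.values()), dtype=float)
        label = res.variant.value
        if res.variant.value == "c_network_gaussian_huff":
            label += f":{res.huff_reading.value}"
        rows.append(
            {
                "variant": label,
                "mean": float(a.mean()),
                "min": float(a.min()),
                "max": float(a.max()),
                "sd": float(a.std(ddof=0)),
            }
        )
    return pd.DataFrame(rows, columns=["variant", "mean", "min", "max", "sd"])
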