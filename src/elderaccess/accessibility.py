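"""The improved 2SFCA model core.

The two-step floating catchment area (2SFCA) score is computed in two
passes over a within-threshold OD matrix:

Step 1 — for each facility *j*, the supply–population ratio

    R_j = S_j / sum_{k : d_kj <= d0} P_k f(d_kj)

where ``S_j`` is facility capacity, ``P_k`` the elderly population at
demand point *k*, and ``f`` a distance-decay kernel.

Step 2 — for each demand point *i*, the accessibility score
``A_i = sum_{j : d_ij <= d0} f(d_ij) R_j``.

The improved model adds Huff destination-choice probabilities

    Prob_ij = S_j f(d_ij) / sum_{k : d_ik <= d0} S_k f(d_ik)

which discount each facility's catchment population by the probability
that it actually chooses that facility, giving the Huff-adjusted ratio
(``R_j = S_j / sum_k P_k f(d_kj) Prob_kj``) and the probability-weighted
score.  Three named variants mirror the standard comparison:

* ``A_BASELINE`` — Euclidean distances, dichotomous (binary) decay, no
  choice probability: the classical 2SFCA before optimization.
* ``B_NETWORK_GAUSSIAN`` — network shortest-path distances with Gaussian
  decay.
* ``C_NETWORK_GAUSSIAN_HUFF`` — network distances, Gaussian decay and Huff
  probabilities.

For variant C two readings of the scoring formula are provided (see
:class:`HuffReading`): the LITERAL reading applies the decay weight in
both steps, as the combined formula prints it; the CONSERVATIVE reading
applies it once, which makes total delivered access exactly conserve
total supply.  Both are exposed; LITERAL is the default.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field as dc_field
from typing import Dict, Hashable, List, Mapping, Sequence, Set, Tuple

from .decay import DecayKind, DecaySpec
from .network import ODMatrix

__all__ = [
    "Facility",
    "DemandPoint",
    "ModelVariant",
    "HuffReading",
    "AccessibilityResult",
    "supply_demand_ratio",
    "huff_probabilities",
    "huff_adjusted_ratio",
    "accessibility_score",
    "oracle_accessibility",
]


@dataclass(frozen=True)
class Facility:
    """A supply point: an elderly care facility.

    ``capacity`` is the supply level S_j — bed count, optionally scaled by
    a service-quality multiplier (``beds * quality``).
    """

    id: Hashable
    x: float
    y: float
    capacity: float

    def __post_init__(self) -> None:
        if not (self.capacity > 0 and math.isfinite(self.capacity)):
            raise ValueError(f"facility {self.id}: capacity must be positive and finite")

    @property
    def location(self) -> Tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class DemandPoint:
    """A residential point or zone centroid with its elderly population P_k."""

    id: Hashable
    x: float
    y: float
    population: float

    def __post_init__(self) -> None:
        if not (self.population >= 0 and math.isfinite(self.population)):
            raise ValueError(f"demand point {self.id}: population must be nonnegative and finite")

    @property
    def location(self) -> Tuple[float, float]:
        return (self.x, self.y)


class ModelVariant(str, enum.Enum):
    """The three model variants of the standard comparison."""

    A_BASELINE = "a_baseline"
    B_NETWORK_GAUSSIAN = "b_network_gaussian"
    C_NETWORK_GAUSSIAN_HUFF = "c_network_gaussian_huff"


class HuffReading(str, enum.Enum):
    """How the decay weight enters the Huff-adjusted score (variant C only).

    LITERAL applies ``f(d_ij)`` in both the ratio numerator and the score
    sum, as the combined two-step formula prints it.  CONSERVATIVE applies
    it once (score ``= sum_j Prob_ij f(d_ij) R_j`` with the Huff-adjusted
    ``R_j``), which satisfies exact supply conservation
    ``sum_i P_i A_i = sum_{served j} S_j``.
    """

    LITERAL = "literal"
    CONSERVATIVE = "conservative"


@dataclass
class AccessibilityResult:
    """Everything one model run produces.

    Attributes
    ----------
    facility_ratio:
        Map facility id -> supply–population ratio R_j (0 for unserviced
        facilities).
    choice_prob:
        Sparse map ``(demand id, facility id) -> Prob_ij`` (empty except
        under variant C).
    access:
        Map demand id -> accessibility score A_i (0 for demand points with
        an empty catchment).
    unserviced:
        Facility ids whose catchment contains no decay-weighted population
        (denominator 0; their R_j is recorded as 0).
    """

    facility_ratio: Dict[Hashable, float]
    choice_prob: Dict[Tuple[Hashable, Hashable], float]
    access: Dict[Hashable, float]
    variant: ModelVariant
    huff_reading: HuffReading
    od: ODMatrix
    unserviced: Set[Hashable] = dc_field(default_factory=set)


def _check_ids(
    facilities: Sequence[Facility], demand: Sequence[DemandPoint], od: ODMatrix
) -> Tuple[Dict[Hashable, Facility], Dict[Hashable, DemandPoint]]:
    fmap = {f.id: f for f in facilities}
    dmap = {d.id: d for d in demand}
    if len(fmap) != len(facilities):
        raise ValueError("duplicate facility ids")
    if len(dmap) != len(demand):
        raise ValueError("duplicate demand ids")
    stray = [(i, j) for (i, j) in od.entries if i not in dmap or j not in fmap]
    if stray:
        raise ValueError(f"OD entries reference unknown ids: {stray[:5]}")
    return fmap, dmap


def _weights_by_facility(
    od: ODMatrix, decay: DecaySpec
) -> Dict[Hashable, List[Tuple[Hashable, float]]]:
    """For each facility, the (demand id, decay weight) pairs in its catchment."""
    out: Dict[Hashable, List[Tuple[Hashable, float]]] = {}
    for (i, j), d in od.entries.items():
        out.setdefault(j, []).append((i, decay(d)))
    return out


def supply_demand_ratio(
    facilities: Sequence[Facility],
    demand: Sequence[DemandPoint],
    od: ODMatrix,
    decay: DecaySpec,
) -> Dict[Hashable, float]:
    """Step-1 supply–population ratios R_j = S_j / sum_k P_k f(d_kj).

    Facilities whose decay-weighted catchment population is zero (no
    demand within ``d0``, or all weights 0) get ``R_j = 0``; callers that
    need the "unserviced" flag use :func:`accessibility_score`, which
    records those ids in the result metadata.
    """
    fmap, dmap = _check_ids(facilities, demand, od)
    by_fac = _weights_by_facility(od, decay)
    ratios: Dict[Hashable, float] = {}
    for fid, fac in fmap.items():
        denom = sum(dmap[i].population * w for i, w in by_fac.get(fid, []))
        ratios[fid] = fac.capacity / denom if denom > 0 else 0.0
    return ratios


def huff_probabilities(
    facilities: Sequence[Facility],
    demand: Sequence[DemandPoint],
    od: ODMatrix,
    decay: DecaySpec,
) -> Dict[Tuple[Hashable, Hashable], float]:
    """Huff choice probabilities Prob_ij, normalized over reachable facilities.

    Rows (demand points) with an empty catchment produce no entries.
    """
    fmap, _dmap = _check_ids(facilities, demand, od)
    raw: Dict[Hashable, List[Tuple[Hashable, float]]] = {}
    for (i, j), d in od.entries.items():
        raw.setdefault(i, []).append((j, fmap[j].capacity * decay(d)))
    probs: Dict[Tuple[Hashable, Hashable], float] = {}
    for i, pairs in raw.items():
        total = sum(w for _j, w in pairs)
        if total > 0:
            for j, w in pairs:
                probs[(i, j)] = w / total
    return probs


def huff_adjusted_ratio(
    facilities: Sequence[Facility],
    demand: Sequence[DemandPoint],
    od: ODMatrix,
    decay: DecaySpec,
    probs: Mapping[Tuple[Hashable, Hashable], float],
) -> Dict[Hashable, float]:
    """Huff-adjusted ratios R_j = S_j / sum_k P_k f(d_kj) Prob_kj."""
    fmap, dmap = _check_ids(facilities, demand, od)
    denoms: Dict[Hashable, float] = {fid: 0.0 for fid in fmap}
    for (i, j), d in od.entries.items():
        denoms[j] += dmap[i].population * decay(d) * probs.get((i, j), 0.0)
    return {
        fid: (fmap[fid].capacity / denoms[fid] if denoms[fid] > 0 else 0.0) for fid in fmap
    }


def _validate_variant(od: ODMatrix, decay: DecaySpec, variant: ModelVariant) -> None:
    if variant is ModelVariant.A_BASELINE:
        if od.metric != "euclidean" or decay.kind is not DecayKind.BINARY:
            raise ValueError(
                "variant A (baseline) requires Euclidean OD distances with binary decay; "
                f"got metric={od.metric!r}, decay={decay.kind.value!r}"
            )
    else:
        if od.metric != "network" or decay.kind is not DecayKind.GAUSSIAN:
            raise ValueError(
                f"variant {variant.name} requires network OD distances with Gaussian decay; "
                f"got metric={od.metric!r}, decay={decay.kind.value!r}"
            )


def accessibility_score(
    facilities: Sequence[Facility],
    demand: Sequence[DemandPoint],
    od: ODMatrix,
    decay: DecaySpec,
    variant: ModelVariant,
    huff_reading: HuffReading = HuffReading.LITERAL,
) -> AccessibilityResult:
    """Run one model variant end to end and return the full result.

    Variant A sums plain step-1 ratios over the Euclidean catchment;
    variant B decay-weights Gaussian step-1 ratios over the network
    catchment; variant C additionally applies Huff choice probabilities,
    under either reading of the combined formula (see
    :class:`HuffReading`).
    """
    variant = ModelVariant(variant)
    huff_reading = HuffReading(huff_reading)
    _validate_variant(od, decay, variant)
    fmap, dmap = _check_ids(facilities, demand, od)

    probs: Dict[Tuple[Hashable, Hashable], float] = {}
    if variant is ModelVariant.C_NETWORK_GAUSSIAN_HUFF:
        probs = huff_probabilities(facilities, demand, od, decay)
        ratios = huff_adjusted_ratio(facilities, demand, od, decay, probs)
        # denominators of the adjusted ratio, needed for the LITERAL score
        denoms: Dict[Hashable, float] = {fid: 0.0 for fid in fmap}
        for (i, j), d in od.entries.items():
            denoms[j] += dmap[i].population * decay(d) * probs.get((i, j), 0.0)
    else:
        ratios = supply_demand_ratio(facilities, demand, od, decay)
        denoms = {
            fid: sum(dmap[i].population * w for i, w in pairs)
            for fid, pairs in _weights_by_facility(od, decay).items()
        }
        denoms = {fid: denoms.get(fid, 0.0) for fid in fmap}

    unserviced = {fid for fid, dn in denoms.items() if dn <= 0}

    access: Dict[Hashable, float] = {did: 0.0 for did in dmap}
    for (i, j), d in od.entries.items():
        w = decay(d)
        if variant is ModelVariant.C_NETWORK_GAUSSIAN_HUFF:
            p = probs.get((i, j), 0.0)
            if huff_reading is HuffReading.LITERAL:
                # decay applied in both steps, as the combined formula prints it
                if denoms[j] > 0:
                    access[i] += p * w * fmap[j].capacity * w / denoms[j]
            else:
                access[i] += p * w * ratios[j]
        else:
            access[i] += w * ratios[j]

    return AccessibilityResult(
        facility_ratio=ratios,
        choice_prob=probs,
        access=access,
        variant=variant,
        huff_reading=huff_reading,
        od=od,
        unserviced=unserviced,
    )


#: Size guard for the brute-force oracle (demand x facility).
ORACLE_MAX_DEMAND = 200
ORACLE_MAX_FACILITIES = 50


def oracle_accessibility(
    facilities: Sequence[Facility],
    demand: Sequence[DemandPoint],
    od: ODMatrix,
    decay: DecaySpec,
    variant: ModelVariant,
    huff_reading: HuffReading = HuffReading.LITERAL,
) -> AccessibilityResult:
    """Naive dense reimplementation of :func:`accessibility_score`.

    Triple-loops over every demand x facility pair with no sparsity or
    shared intermediates; used only in tests as an independent check.
    Guarded to small instances.
    """
    variant = ModelVariant(variant)
    huff_reading = HuffReading(huff_reading)
    if len(demand) > ORACLE_MAX_DEMAND or len(facilities) > ORACLE_MAX_FACILITIES:
        raise ValueError(
            f"oracle size guard exceeded ({len(demand)} demand x {len(facilities)} facilities)"
        )
    _validate_variant(od, decay, variant)
    _check_ids(facilities, demand, od)

    def dist(i, j):
        return od.entries.get((i, j))

    def f(i, j):
        d = dist(i, j)
        return 0.0 if d is None else decay(d)

    # Huff probabilities, row by row
    probs: Dict[Tuple[Hashable, Hashable], float] = {}
    if variant is ModelVariant.C_NETWORK_GAUSSIAN_HUFF:
        for dp in demand:
            row_total = 0.0
            for fac in facilities:
                row_total += fac.capacity * f(dp.id, fac.id)
            if row_total > 0:
                for fac in facilities:
                    if dist(dp.id, fac.id) is not None:
                        probs[(dp.id, fac.id)] = fac.capacity * f(dp.id, fac.id) / row_total

    # step-1 denominators and ratios
    ratios: Dict[Hashable, float] = {}
    denoms: Dict[Hashable, float] = {}
    unserviced: Set[Hashable] = set()
    for fac in facilities:
        denom = 0.0
        for dp in demand:
            w = f(dp.id, fac.id)
            if variant is ModelVariant.C_NETWORK_GAUSSIAN_HUFF:
                w *= probs.get((dp.id, fac.id), 0.0)
            denom += dp.population * w
        denoms[fac.id] = denom
        if denom > 0:
            ratios[fac.id] = fac.capacity / denom
        else:
            ratios[fac.id] = 0.0
            unserviced.add(fac.id)

    # step-2 scores
    access: Dict[Hashable, float] = {}
    for dp in demand:
        a = 0.0
        for fac in facilities:
            if dist(dp.id, fac.id) is None:
                continue
            w = f(dp.id, fac.id)
            if variant is ModelVariant.C_NETWORK_GAUSSIAN_HUFF:
                p = probs.get((dp.id, fac.id), 0.0)
                if huff_reading is HuffReading.LITERAL:
                    if denoms[fac.id] > 0:
                        a += p * w * fac.capacity * w / denoms[fac.id]
                else:
                    a += p * w * ratios[fac.id]
            else:
                a += w * ratios[fac.id]
        access[dp.id] = a

    return AccessibilityResult(
        facility_ratio=ratios,
        choice_prob=probs,
        access=access,
        variant=variant,
        huff_reading=huff_reading,
        od=od,
        unserviced=unserviced,
    )
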