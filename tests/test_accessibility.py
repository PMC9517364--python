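import math

import pytest

from conftest import run_all_variants
from elderaccess import (
    DecayKind,
    DecaySpec,
    DemandPoint,
    Facility,
    HuffReading,
    ModelVariant,
    ODMatrix,
    accessibility_score,
    huff_adjusted_ratio,
    huff_probabilities,
    oracle_accessibility,
    supply_demand_ratio,
)

D0 = 800.0
GAUSS = DecaySpec(DecayKind.GAUSSIAN, D0)
BINARY = DecaySpec(DecayKind.BINARY, D0)


def od_of(entries, metric="network"):
    return ODMatrix(entries=dict(entries), d0=D0, metric=metric)


def test_supply_demand_ratio_direct_substitution():
    fac = [Facility("f", 0, 0, capacity=50.0)]
    dem = [DemandPoint("d", 0, 0, population=100.0)]
    ratios = supply_demand_ratio(fac, dem, od_of({("d", "f"): 0.0}), GAUSS)
    assert ratios["f"] == pytest.approx(0.5)


def test_supply_demand_ratio_boundary_demand_carries_zero_weight():
    fac = [Facility("f", 0, 0, capacity=90.0)]
    dem = [DemandPoint("d1", 0, 0, population=30.0),
           DemandPoint("d2", 0, 0, population=40.0)]
    od = od_of({("d1", "f"): 0.0, ("d2", "f"): D0})  # d2 sits exactly on the boundary
    assert supply_demand_ratio(fac, dem, od, GAUSS)["f"] == pytest.approx(3.0)


def test_facility_with_empty_catchment_is_unserviced_with_zero_ratio():
    fac = [Facility("f", 0, 0, capacity=50.0)]
    dem = [DemandPoint("d", 0, 0, population=100.0)]
    res = accessibility_score(fac, dem, od_of({}), GAUSS, ModelVariant.B_NETWORK_GAUSSIAN)
    assert res.facility_ratio["f"] == 0.0
    assert res.unserviced == {"f"}
    assert res.access["d"] == 0.0


@pytest.mark.parametrize(
    "capacities, expected",
    [((10.0, 30.0), (0.25, 0.75)), ((20.0, 20.0), (0.5, 0.5))],
)
def test_huff_probabilities_proportional_to_capacity(capacities, expected):
    fac = [Facility("f1", 0, 0, capacities[0]), Facility("f2", 0, 0, capacities[1])]
    dem = [DemandPoint("d", 0, 0, 100.0)]
    probs = huff_probabilities(fac, dem, od_of({("d", "f1"): 0.0, ("d", "f2"): 0.0}), GAUSS)
    assert probs[("d", "f1")] == pytest.approx(expected[0])
    assert probs[("d", "f2")] == pytest.approx(expected[1])


def test_huff_single_reachable_facility_gets_probability_one():
    fac = [Facility("f1", 0, 0, 10.0), Facility("f2", 0, 0, 99.0)]
    dem = [DemandPoint("d", 0, 0, 100.0)]
    probs = huff_probabilities(fac, dem, od_of({("d", "f1"): 100.0}), GAUSS)
    assert probs == {("d", "f1"): pytest.approx(1.0)}


def test_huff_adjusted_ratio_reduces_to_plain_ratio_with_one_facility():
    fac = [Facility("f", 0, 0, 50.0)]
    dem = [DemandPoint("d", 0, 0, 100.0)]
    od = od_of({("d", "f"): 0.0})
    probs = huff_probabilities(fac, dem, od, GAUSS)
    assert huff_adjusted_ratio(fac, dem, od, GAUSS, probs)["f"] == pytest.approx(0.5)


def test_huff_adjusted_ratio_scales_denominator_by_choice_probability():
    # one demand point splits 0.25 / 0.75 between two co-located facilities
    fac = [Facility("f1", 0, 0, 10.0), Facility("f2", 0, 0, 30.0)]
    dem = [DemandPoint("d", 0, 0, 100.0)]
    od = od_of({("d", "f1"): 0.0, ("d", "f2"): 0.0})
    probs = huff_probabilities(fac, dem, od, GAUSS)
    ratios = huff_adjusted_ratio(fac, dem, od, GAUSS, probs)
    assert ratios["f1"] == pytest.approx(10.0 / (100.0 * 0.25))
    assert ratios["f2"] == pytest.approx(30.0 / (100.0 * 0.75))


@pytest.mark.parametrize(
    "variant, reading",
    [
        (ModelVariant.A_BASELINE, HuffReading.LITERAL),
        (ModelVariant.B_NETWORK_GAUSSIAN, HuffReading.LITERAL),
        (ModelVariant.C_NETWORK_GAUSSIAN_HUFF, HuffReading.LITERAL),
        (ModelVariant.C_NETWORK_GAUSSIAN_HUFF, HuffReading.CONSERVATIVE),
    ],
)
def test_single_pair_at_zero_distance_gives_supply_per_capita(variant, reading):
    fac = [Facility("f", 0, 0, 50.0)]
    dem = [DemandPoint("d", 0, 0, 200.0)]
    metric = "euclidean" if variant is ModelVariant.A_BASELINE else "network"
    decay = BINARY if variant is ModelVariant.A_BASELINE else GAUSS
    res = accessibility_score(fac, dem, od_of({("d", "f"): 0.0}, metric), decay, variant, reading)
    assert res.access["d"] == pytest.approx(0.25)


def test_linear_city_expected_values(linear_city):
    """Frozen expectations of the 5-node path-graph instance, all variants."""
    from elderaccess import euclidean_od, od_distances, snap_points

    net, facilities, demand, expected = linear_city
    fac_nodes = snap_points({f.id: f.location for f in facilities}, net, 1.0)
    dem_nodes = snap_points({d.id: d.location for d in demand}, net, 1.0)
    od_net = od_distances(dem_nodes, fac_nodes, net, D0)
    od_euc = euclidean_od({d.id: d.location for d in demand},
                          {f.id: f.location for f in facilities}, D0)
    runs = {
        "a": accessibility_score(facilities, demand, od_euc, BINARY, ModelVariant.A_BASELINE),
        "b": accessibility_score(facilities, demand, od_net, GAUSS, ModelVariant.B_NETWORK_GAUSSIAN),
        "c_literal": accessibility_score(
            facilities, demand, od_net, GAUSS, ModelVariant.C_NETWORK_GAUSSIAN_HUFF, "literal"),
        "c_conservative": accessibility_score(
            facilities, demand, od_net, GAUSS, ModelVariant.C_NETWORK_GAUSSIAN_HUFF, "conservative"),
    }
    for key, res in runs.items():
        for did, a in expected[key]["access"].items():
            assert res.access[did] == pytest.approx(a, rel=1e-12), (key, did)
        for fid, r in expected[key]["facility_ratio"].items():
            assert res.facility_ratio[fid] == pytest.approx(r, rel=1e-12), (key, fid)
        for pair, p in expected[key].get("choice_prob", {}).items():
            assert res.choice_prob[pair] == pytest.approx(p, rel=1e-12), (key, pair)


def test_variant_metric_mismatch_is_an_error():
    fac = [Facility("f", 0, 0, 50.0)]
    dem = [DemandPoint("d", 0, 0, 100.0)]
    with pytest.raises(ValueError, match="variant"):
        accessibility_score(fac, dem, od_of({}, "network"), GAUSS, ModelVariant.A_BASELINE)
    with pytest.raises(ValueError, match="variant"):
        accessibility_score(fac, dem, od_of({}, "euclidean"), BINARY,
                            ModelVariant.B_NETWORK_GAUSSIAN)


def test_unknown_od_ids_are_an_error():
    fac = [Facility("f", 0, 0, 50.0)]
    dem = [DemandPoint("d", 0, 0, 100.0)]
    with pytest.raises(ValueError, match="unknown ids"):
        supply_demand_ratio(fac, dem, od_of({("ghost", "f"): 0.0}), GAUSS)


def test_empty_entity_lists():
    fac = [Facility("f", 0, 0, 50.0)]
    dem = [DemandPoint("d", 0, 0, 100.0)]
    res = oracle_accessibility([], dem, od_of({}), GAUSS, ModelVariant.B_NETWORK_GAUSSIAN)
    assert res.access == {"d": 0.0}
    res = oracle_accessibility(fac, [], od_of({}), GAUSS, ModelVariant.B_NETWORK_GAUSSIAN)
    assert res.unserviced == {"f"}


# ---------------------------------------------------------------------------
# model-level invariants on synthetic cities
# ---------------------------------------------------------------------------

SEEDS = range(12)


@pytest.mark.parametrize("seed", SEEDS)
def test_huff_rows_sum_to_one(seed):
    runs, _, _ = run_all_variants(seed)
    res = runs["c_literal"]
    rows = {}
    for (i, _j), p in res.choice_prob.items():
        rows[i] = rows.get(i, 0.0) + p
    assert rows, "expected at least one nonempty catchment"
    for i, total in rows.items():
        assert total == pytest.approx(1.0, abs=1e-12), i


@pytest.mark.parametrize("seed", SEEDS)
def test_supply_conservation(seed):
    """Total delivered access equals total served supply (variants B, C-cons)."""
    runs, facilities, demand = run_all_variants(seed)
    pop = {d.id: d.population for d in demand}
    cap = {f.id: f.capacity for f in facilities}
    for key in ("b", "c_conservative"):
        res = runs[key]
        delivered = sum(pop[i] * a for i, a in res.access.items())
        served = sum(cap[j] for j in cap if j not in res.unserviced)
        assert delivered == pytest.approx(served, rel=1e-9), key
    # LITERAL reading under-delivers: decay applied twice
    res = runs["c_literal"]
    delivered = sum(pop[i] * a for i, a in res.access.items())
    served = sum(cap[j] for j in cap if j not in res.unserviced)
    assert delivered <= served * (1 + 1e-12)


@pytest.mark.parametrize("seed", range(6))
def test_matches_brute_force_oracle(seed):
    runs, facilities, demand = run_all_variants(seed)
    for key, res in runs.items():
        oracle = oracle_accessibility(
            facilities, demand, res.od,
            DecaySpec(DecayKind.BINARY if key == "a" else DecayKind.GAUSSIAN, D0),
            res.variant, res.huff_reading,
        )
        for i in oracle.access:
            assert res.access[i] == pytest.approx(oracle.access[i], rel=1e-10, abs=1e-15), (key, i)
        for j in oracle.facility_ratio:
            assert res.facility_ratio[j] == pytest.approx(
                oracle.facility_ratio[j], rel=1e-10, abs=1e-15), (key, j)
        assert res.unserviced == oracle.unserviced


def test_single_facility_conservative_huff_reduces_to_variant_b(linear_city):
    net, facilities, demand, _ = linear_city
    from elderaccess import od_distances, snap_points

    fac = [facilities[0]]
    fac_nodes = snap_points({f.id: f.location for f in fac}, net, 1.0)
    dem_nodes = snap_points({d.id: d.location for d in demand}, net, 1.0)
    od = od_distances(dem_nodes, fac_nodes, net, D0)
    res_b = accessibility_score(fac, demand, od, GAUSS, ModelVariant.B_NETWORK_GAUSSIAN)
    res_c = accessibility_score(fac, demand, od, GAUSS,
                                ModelVariant.C_NETWORK_GAUSSIAN_HUFF, "conservative")
    for i in res_b.access:
        assert res_c.access[i] == pytest.approx(res_b.access[i], rel=1e-12)


def test_capacity_increase_weakly_increases_variant_b_scores():
    runs, facilities, demand = run_all_variants(seed=2)
    base = runs["b"]
    target = facilities[0]
    boosted = [Facility(f.id, f.x, f.y, f.capacity * 2 if f.id == target.id else f.capacity)
               for f in facilities]
    res2 = accessibility_score(boosted, demand, base.od, GAUSS, ModelVariant.B_NETWORK_GAUSSIAN)
    reached = {i for (i, j) in base.od.entries if j == target.id}
    for i in base.access:
        assert res2.access[i] >= base.access[i] - 1e-12
        if i in reached and base.od.entries[(i, target.id)] < D0:
            assert res2.access[i] > base.access[i]
    for j in base.facility_ratio:
        if j != target.id:
            assert res2.facility_ratio[j] == pytest.approx(base.facility_ratio[j], rel=1e-12)


@pytest.mark.parametrize("key", ["a", "b", "c_literal", "c_conservative"])
def test_population_scaling_inversely_scales_scores(key):
    runs, facilities, demand = run_all_variants(seed=5)
    base = runs[key]
    c = 3.0
    scaled_dem = [DemandPoint(d.id, d.x, d.y, d.population * c) for d in demand]
    res2 = accessibility_score(
        facilities, scaled_dem, base.od,
        DecaySpec(DecayKind.BINARY if key == "a" else DecayKind.GAUSSIAN, D0),
        base.variant, base.huff_reading,
    )
    for i in base.access:
        assert res2.access[i] == pytest.approx(base.access[i] / c, rel=1e-10, abs=1e-15)


def test_entity_validation():
    with pytest.raises(ValueError, match="capacity"):
        Facility("f", 0, 0, 0.0)
    with pytest.raises(ValueError, match="population"):
        DemandPoint("d", 0, 0, -1.0)
    with pytest.raises(ValueError, match="population"):
        DemandPoint("d", 0, 0, math.inf)


def test_oracle_size_guard():
    dem = [DemandPoint(f"d{i}", 0, 0, 1.0) for i in range(201)]
    with pytest.raises(ValueError, match="size guard"):
        oracle_accessibility([], dem, od_of({}), GAUSS, ModelVariant.B_NETWORK_GAUSSIAN)
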