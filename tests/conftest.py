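import pytest

from elderaccess import (
    CitySpec,
    DecayKind,
    DecaySpec,
    HuffReading,
    ModelVariant,
    accessibility_score,
    euclidean_od,
    generate_city,
    linear_city_fixture,
    od_distances,
    snap_points,
)

#: compact city used wherever a test sweeps many seeds
SMALL_CITY = dict(rows=8, cols=8, spacing_m=250.0, n_facilities=6, n_demand=25)


@pytest.fixture
def linear_city():
    """The hard-coded 5-node path-graph instance with frozen expectations."""
    return linear_city_fixture()


def build_city(seed: int, **overrides):
    """Generate a small synthetic city and snap entities to the network."""
    spec = CitySpec(seed=seed, **{**SMALL_CITY, **overrides})
    net, facilities, demand = generate_city(spec)
    tol = spec.spacing_m / 2
    fac_nodes = snap_points({f.id: f.location for f in facilities}, net, tol)
    dem_nodes = snap_points({d.id: d.location for d in demand}, net, tol)
    return net, facilities, demand, fac_nodes, dem_nodes


def run_all_variants(seed: int, d0: float = 800.0, **overrides):
    """All three model variants (plus both Huff readings) on one city."""
    net, facilities, demand, fac_nodes, dem_nodes = build_city(seed, **overrides)
    od_net = od_distances(dem_nodes, fac_nodes, net, d0)
    od_euc = euclidean_od(
        {d.id: d.location for d in demand}, {f.id: f.location for f in facilities}, d0
    )
    gauss = DecaySpec(DecayKind.GAUSSIAN, d0)
    binary = DecaySpec(DecayKind.BINARY, d0)
    return {
        "a": accessibility_score(facilities, demand, od_euc, binary, ModelVariant.A_BASELINE),
        "b": accessibility_score(facilities, demand, od_net, gauss, ModelVariant.B_NETWORK_GAUSSIAN),
        "c_literal": accessibility_score(
            facilities, demand, od_net, gauss, ModelVariant.C_NETWORK_GAUSSIAN_HUFF, HuffReading.LITERAL
        ),
        "c_conservative": accessibility_score(
            facilities, demand, od_net, gauss, ModelVariant.C_NETWORK_GAUSSIAN_HUFF, HuffReading.CONSERVATIVE
        ),
    }, facilities, demand
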