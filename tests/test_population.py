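"""mtDNA allocation, spatial placement and pre-division diffusion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mitopart import (
    CellGeometry,
    DiffusionParams,
    GeneticParams,
    GrowthParams,
    PlacementParams,
    allocate_counts,
    diffuse,
    grow_network,
    make_fixture,
    place_population,
    random_walk_displacements,
)
from mitopart.population import NETWORK, population_to_frame


class TestAllocation:
    @pytest.mark.parametrize(
        "params, expected",
        [
            ((100, 0.1, 1.0, 0.0), (90, 0, 0, 10)),
            ((100, 0.5, 0.5, 0.5), (25, 25, 25, 25)),
            ((101, 0.5, 1.0, 1.0), (51, 0, 50, 0)),  # half rounds away from zero
            ((100, 0.0, 0.3, 0.9), (30, 70, 0, 0)),
        ],
    )
    def test_examples(self, params, expected):
        assert allocate_counts(GeneticParams(*params)) == expected

    @given(
        N0=st.integers(1, 5000),
        h=st.floats(0, 1),
        p=st.floats(0, 1),
        q=st.floats(0, 1),
    )
    @settings(max_examples=200, derandomize=True)
    def test_totals_conserved_and_nonnegative(self, N0, h, p, q):
        a = allocate_counts(GeneticParams(N0, h, p, q))
        assert min(a) >= 0
        assert a.N0 == N0
        w_total = round(math.floor((1 - h) * N0 + 0.5))
        assert a.w_n + a.w_c == w_total
        assert a.m_n + a.m_c == N0 - w_total

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            GeneticParams(0, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            GeneticParams(10, 1.5, 0.5, 0.5)


class TestPlacement:
    def test_counts_and_compartments(self, rng):
        net = make_fixture("cross")
        popn = place_population(net, allocate_counts(GeneticParams(100, 0.1, 1.0, 0.0)),
                                PlacementParams(), rng)
        c = popn.counts()
        assert (c.w_n, c.w_c, c.m_n, c.m_c) == (90, 0, 0, 10)
        on_net = popn.positions[popn.compartment == NETWORK]
        # cross fixture: networked molecules sit on one of the two axes
        assert np.all(np.minimum(np.abs(on_net[:, 0]), np.abs(on_net[:, 1])) < 1e-9)

    def test_cytoplasmic_molecules_are_area_uniform(self, rng):
        popn = place_population(None, allocate_counts(GeneticParams(20000, 0.5, 0.0, 0.0)),
                                PlacementParams(), rng)
        r2 = np.einsum("ij,ij->i", popn.positions, popn.positions)
        assert r2.max() <= 1.0
        assert r2.mean() == pytest.approx(0.5, abs=3.5 * r2.std() / math.sqrt(len(r2)))

    def test_empty_network_with_networked_molecules_raises(self, rng):
        with pytest.raises(ValueError):
            place_population(None, allocate_counts(GeneticParams(10, 0.5, 1.0, 1.0)),
                             PlacementParams(), rng)

    def test_repulsive_spacing_on_diameter(self, rng):
        # 4 molecules fit comfortably on a length-2 chord at spacing 0.4
        # (even l = 0.5 has a valid configuration: -0.75, -0.25, 0.25, 0.75)
        net = make_fixture("diameter")
        alloc = allocate_counts(GeneticParams(4, 0.5, 1.0, 1.0))
        popn = place_population(net, alloc, PlacementParams("repulsive", l=0.4), rng)
        assert popn.relaxation_events == 0  # holds for this seed
        d = np.linalg.norm(popn.positions[:, None] - popn.positions[None, :], axis=-1)
        assert d[np.triu_indices(4, 1)].min() >= 0.4

    def test_repulsive_spacing_on_grown_network(self, rng):
        net = grow_network(CellGeometry(), GrowthParams(s=64), rng)
        alloc = allocate_counts(GeneticParams(100, 0.5, 1.0, 1.0))
        popn = place_population(net, alloc, PlacementParams("repulsive", l=0.1), rng)
        pos = popn.positions[popn.compartment == NETWORK]
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        if popn.relaxation_events == 0:
            assert d[np.triu_indices(len(pos), 1)].min() >= 0.1

    def test_repulsive_with_zero_radius_behaves_like_random(self, rng):
        net = make_fixture("ring")
        alloc = allocate_counts(GeneticParams(50, 0.5, 1.0, 1.0))
        popn = place_population(net, alloc, PlacementParams("repulsive", l=0.0), rng)
        assert popn.relaxation_events == 0
        assert len(popn) == 50

    def test_infeasible_spacing_triggers_relaxation(self, rng):
        net = make_fixture("diameter")  # length 2 cannot hold 10 points at l=0.5
        alloc = allocate_counts(GeneticParams(10, 0.5, 1.0, 1.0))
        popn = place_population(net, alloc, PlacementParams("repulsive", l=0.5, max_attempts=64),
                                rng)
        assert popn.relaxation_events > 0

    def test_export_frame(self, rng):
        popn = place_population(make_fixture("cross"),
                                allocate_counts(GeneticParams(10, 0.5, 1.0, 0.0)),
                                PlacementParams(), rng)
        df = population_to_frame(popn)
        assert set(df.columns) == {"x", "y", "genotype", "compartment"}
        assert len(df) == 10


class TestDiffusion:
    def test_zero_scale_leaves_positions_unchanged(self, rng):
        popn = place_population(make_fixture("cross"),
                                allocate_counts(GeneticParams(50, 0.5, 1.0, 1.0)),
                                PlacementParams(), rng)
        moved = diffuse(popn, DiffusionParams(lam=0.0), rng)
        assert np.array_equal(moved.positions, popn.positions)

    def test_counts_conserved_and_confined(self, rng):
        popn = place_population(make_fixture("cross"),
                                allocate_counts(GeneticParams(200, 0.3, 0.8, 0.2)),
                                PlacementParams(), rng)
        moved = diffuse(popn, DiffusionParams(lam=0.05), rng)
        assert moved.counts() == popn.counts()
        r = np.hypot(moved.positions[:, 0], moved.positions[:, 1])
        assert r.max() <= 1.0 + 1e-12

    def test_unconfined_rms_displacement_is_10_lambda(self, rng):
        """100 steps of RMS length lam give net RMS displacement 10 lam."""
        lam = 0.03
        disp = random_walk_displacements(10000, DiffusionParams(lam=lam, n_steps=100), rng)
        rms = np.sqrt(np.mean(np.einsum("ij,ij->i", disp, disp)))
        assert rms / lam == pytest.approx(10.0, rel=0.05)

    def test_strong_diffusion_uniformises_networked_molecules(self, rng):
        """For lam >= 0.5 the network imprint washes out to area-uniformity."""
        net = grow_network(CellGeometry(), GrowthParams(s=4), rng)
        popn = place_population(net, allocate_counts(GeneticParams(10000, 0.5, 1.0, 1.0)),
                                PlacementParams(), rng)
        moved = diffuse(popn, DiffusionParams(lam=0.5), rng)
        r2 = np.einsum("ij,ij->i", moved.positions, moved.positions)
        # area-uniform disc has ||v||^2 ~ Uniform(0, 1)
        assert stats.kstest(r2, "uniform").pvalue > 0.01

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            DiffusionParams(lam=-0.1)
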