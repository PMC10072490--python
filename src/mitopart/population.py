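"""mtDNA populations: allocation, spatial placement and pre-division diffusion.

A mother cell carries ``N0`` mtDNA molecules at heteroplasmy ``h`` (fraction
mutant).  A proportion ``p`` of wildtype and ``q`` of mutant molecules reside
in the reticulated network; the remainder sit in fragmented organelles spread
area-uniformly through the cytoplasm.  Networked molecules are placed either
uniformly by arc length, or with a mutual-repulsion "halo": no two networked
molecules may sit within Euclidean distance ``l`` of each other.

Optionally, the network fragments before division and every molecule performs
a confined random walk of ``n_steps`` isotropic Gaussian steps of RMS length
``lam``, so the expected net displacement is ``sqrt(n_steps) * lam`` (10*lam
for the default 100 steps, boundary effects aside).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Literal, NamedTuple

import numpy as np

from .network import NetworkStructure, sample_network_point

__all__ = [
    "GeneticParams",
    "CountAllocation",
    "PlacementParams",
    "DiffusionParams",
    "Molecule",
    "MtDNAPopulation",
    "allocate_counts",
    "place_population",
    "diffuse",
    "random_walk_displacements",
]

WILDTYPE, MUTANT = 0, 1
NETWORK, CYTOPLASM = 0, 1


@dataclass(frozen=True)
class GeneticParams:
    """Mother-cell genetic state: copy number and network-inclusion biases."""

    N0: int
    h: float
    p: float
    q: float

    def __post_init__(self) -> None:
        if self.N0 < 1:
            raise ValueError("N0 must be a positive integer")
        for name in ("h", "p", "q"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


class CountAllocation(NamedTuple):
    """Integer molecule counts by genotype (w/m) and compartment (n/c)."""

    w_n: int
    w_c: int
    m_n: int
    m_c: int

    @property
    def N0(self) -> int:
        return self.w_n + self.w_c + self.m_n + self.m_c

    @property
    def networked(self) -> int:
        return self.w_n + self.m_n


@dataclass(frozen=True)
class PlacementParams:
    mode: Literal["random", "repulsive"] = "random"
    l: float = 0.0
    max_attempts: int = 1000

    def __post_init__(self) -> None:
        if self.l < 0:
            raise ValueError("exclusion radius l must be non-negative")
        if self.mode not in ("random", "repulsive"):
            raise ValueError(f"unknown placement mode {self.mode!r}")


@dataclass(frozen=True)
class DiffusionParams:
    """Pre-division fragmentation-and-diffusion: ``n_steps`` steps of RMS length lam.

    step_convention "rms": per-axis sigma = lam / sqrt(2), so the RMS step
    length is lam and the 100-step RMS displacement is exactly 10*lam.
    step_convention "per_axis": per-axis sigma = lam.
    """

    lam: float = 0.0
    n_steps: int = 100
    step_convention: Literal["rms", "per_axis"] = "rms"
    boundary: Literal["reject", "resample"] = "reject"

    def __post_init__(self) -> None:
        if self.lam < 0 or self.n_steps < 0:
            raise ValueError("lam and n_steps must be non-negative")

    @property
    def sigma_axis(self) -> float:
        return self.lam / math.sqrt(2.0) if self.step_convention == "rms" else self.lam


class Molecule(NamedTuple):
    position: np.ndarray
    genotype: int
    compartment: int


@dataclass
class MtDNAPopulation:
    """Array-backed set of molecules with genotype and compartment labels."""

    positions: np.ndarray  # (N, 2)
    genotype: np.ndarray  # (N,) 0 = wildtype, 1 = mutant
    compartment: np.ndarray  # (N,) 0 = network, 1 = cytoplasm
    relaxation_events: int = 0

    def __len__(self) -> int:
        return len(self.genotype)

    def __iter__(self) -> Iterator[Molecule]:
        for i in range(len(self)):
            yield Molecule(self.positions[i], int(self.genotype[i]), int(self.compartment[i]))

    def counts(self) -> CountAllocation:
        wt = self.genotype == WILDTYPE
        net = self.compartment == NETWORK
        return CountAllocation(
            w_n=int(np.sum(wt & net)),
            w_c=int(np.sum(wt & ~net)),
            m_n=int(np.sum(~wt & net)),
            m_c=int(np.sum(~wt & ~net)),
        )


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def allocate_counts(gp: GeneticParams) -> CountAllocation:
    """Deterministic integer allocation of molecules to genotype/compartment.

    ``w_n = p (1-h) N0`` etc., rounded half away from zero with complements
    taken by subtraction so all totals are conserved exactly.
    """
    w_total = _round_half_away((1.0 - gp.h) * gp.N0)
    m_total = gp.N0 - w_total
    w_n = _round_half_away(gp.p * w_total)
    m_n = _round_half_away(gp.q * m_total)
    return CountAllocation(w_n=w_n, w_c=w_total - w_n, m_n=m_n, m_c=m_total - m_n)


def _uniform_disc(rng: np.random.Generator, n: int) -> np.ndarray:
    r = np.sqrt(rng.uniform(0.0, 1.0, size=n))
    th = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _place_repulsive(
    net: NetworkStructure, n: int, l: float, max_attempts: int, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Sequential placement on the network with a minimum-distance halo.

    Each molecule gets up to ``max_attempts`` uniformly sampled candidates;
    the first candidate at distance >= l from every placed molecule is
    accepted.  If all candidates fail, the one with the largest
    nearest-neighbour distance is accepted and a relaxation event counted.
    """
    placed = np.empty((n, 2))
    relaxations = 0
    l2 = l * l
    batch = 32
    for i in range(n):
        if i == 0:
            placed[0] = sample_network_point(net, rng)
            continue
        best, best_d2 = None, -1.0
        accepted = False
        attempts = 0
        while attempts < max_attempts:
            m = min(batch, max_attempts - attempts)
            cand = sample_network_point(net, rng, size=m)
            attempts += m
            diff = cand[:, None, :] - placed[None, :i, :]
            d2 = np.min(np.einsum("ijk,ijk->ij", diff, diff), axis=1)
            ok = np.flatnonzero(d2 >= l2)
            if ok.size:
                placed[i] = cand[ok[0]]
                accepted = True
                break
            j = int(np.argmax(d2))
            if d2[j] > best_d2:
                best_d2, best = float(d2[j]), cand[j]
        if not accepted:
            placed[i] = best
            relaxations += 1
    return placed, relaxations


def place_population(
    net: NetworkStructure | None,
    alloc: CountAllocation,
    pp: PlacementParams,
    rng: np.random.Generator,
) -> MtDNAPopulation:
    """Place all molecules: networked on the network, the rest area-uniform."""
    nn = alloc.networked
    nc = alloc.w_c + alloc.m_c
    if nn > 0 and (net is None or net.total_mass <= 0):
        raise ValueError("networked molecules requested but the network is empty")

    genotype = np.concatenate(
        [
            np.full(alloc.w_n, WILDTYPE, dtype=np.int8),
            np.full(alloc.m_n, MUTANT, dtype=np.int8),
            np.full(alloc.w_c, WILDTYPE, dtype=np.int8),
            np.full(alloc.m_c, MUTANT, dtype=np.int8),
        ]
    )
    compartment = np.concatenate(
        [np.full(nn, NETWORK, dtype=np.int8), np.full(nc, CYTOPLASM, dtype=np.int8)]
    )

    relaxations = 0
    if nn > 0:
        if pp.mode == "repulsive" and pp.l > 0:
            # single shuffled order over both genotypes so neither type
            # systematically wins contested space
            order = rng.permutation(nn)
            pts, relaxations = _place_repulsive(net, nn, pp.l, pp.max_attempts, rng)
            net_pts = np.empty((nn, 2))
            net_pts[order] = pts
        else:
            net_pts = sample_network_point(net, rng, size=nn)
    else:
        net_pts = np.empty((0, 2))

    cyto_pts = _uniform_disc(rng, nc)
    return MtDNAPopulation(
        positions=np.concatenate([net_pts, cyto_pts]),
        genotype=genotype,
        compartment=compartment,
        relaxation_events=relaxations,
    )


def random_walk_displacements(
    n_walks: int,
    dp: DiffusionParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Net displacement vectors of unconfined ``n_steps`` random walks.

    The free-space reference for the confined walk in :func:`diffuse`; under
    the "rms" step convention the RMS net displacement is
    ``sqrt(n_steps) * lam`` exactly.
    """
    steps = rng.normal(0.0, dp.sigma_axis, size=(n_walks, dp.n_steps, 2))
    return steps.sum(axis=1)


def diffuse(
    popn: MtDNAPopulation, dp: DiffusionParams, rng: np.random.Generator
) -> MtDNAPopulation:
    """Confined random walk of every molecule (the network has fragmented).

    Each step proposes an isotropic Gaussian displacement.  Under the default
    ``boundary="reject"`` rule a proposal leaving the unit disc is discarded
    and the molecule stays put for that step — the Metropolis-style move
    whose stationary law is exactly area-uniform, so strong diffusion erases
    the network imprint completely.  ``boundary="resample"`` redraws the step
    instead (up to 100 tries), which moves more but weights the interior
    slightly.  Genotype and compartment labels are untouched.
    """
    if dp.lam == 0.0 or dp.n_steps == 0 or len(popn) == 0:
        return MtDNAPopulation(
            positions=popn.positions.copy(),
            genotype=popn.genotype.copy(),
            compartment=popn.compartment.copy(),
            relaxation_events=popn.relaxation_events,
        )
    pos = popn.positions.copy()
    n = len(popn)
    sigma = dp.sigma_axis
    for _ in range(dp.n_steps):
        proposal = pos + rng.normal(0.0, sigma, size=(n, 2))
        outside = np.einsum("ij,ij->i", proposal, proposal) > 1.0
        if dp.boundary == "resample":
            tries = 0
            while outside.any() and tries < 100:
                idx = np.flatnonzero(outside)
                proposal[idx] = pos[idx] + rng.normal(0.0, sigma, size=(idx.size, 2))
                outside[idx] = np.einsum("ij,ij->i", proposal[idx], proposal[idx]) > 1.0
                tries += 1
        proposal[outside] = pos[outside]  # stay put this step
        pos = proposal
    return MtDNAPopulation(
        positions=pos,
        genotype=popn.genotype.copy(),
        compartment=popn.compartment.copy(),
        relaxation_events=popn.relaxation_events,
    )


def population_to_frame(popn: MtDNAPopulation):
    """Export as a DataFrame with columns (x, y, genotype, compartment)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "x": popn.positions[:, 0],
            "y": popn.positions[:, 1],
            "genotype": np.where(popn.genotype == WILDTYPE, "wildtype", "mutant"),
            "compartment": np.where(popn.compartment == NETWORK, "network", "cytoplasm"),
        }
    )
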