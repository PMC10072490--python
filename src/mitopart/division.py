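"""Cell division: sector partitioning and ensemble variance summaries.

Division is modelled by intersecting the cell with a randomly oriented
circular sector of angle ``phi`` (``phi = 180`` degrees is a symmetric
division); the sector daughter inherits the molecules whose polar angle falls
inside it together with the network mass ``u`` of the sector.  Ensembles of
independent realisations yield the quantities of interest: copy number
variance V(N), heteroplasmy variance V(h), its normalised form
V'(h) = V(h) / (h (1 - h)), and the moments of the inherited network
fraction U.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .network import CellGeometry, GrowthParams, NetworkStructure, grow_network
from .population import (
    MUTANT,
    WILDTYPE,
    CountAllocation,
    DiffusionParams,
    GeneticParams,
    MtDNAPopulation,
    PlacementParams,
    allocate_counts,
    diffuse,
    place_population,
)

__all__ = [
    "DivisionParams",
    "DaughterOutcome",
    "EnsembleSummary",
    "partition",
    "run_ensemble",
    "normalized_vh",
]

_TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class DivisionParams:
    """Sector division angle ``phi`` in degrees; phi = 180 is symmetric."""

    phi: float = 180.0

    def __post_init__(self) -> None:
        if not 0.0 < self.phi <= 360.0:
            raise ValueError("phi must lie in (0, 360] degrees")

    @property
    def p_c(self) -> float:
        """Inherited cytoplasm (area) fraction."""
        return self.phi / 360.0

    @classmethod
    def from_p_c(cls, p_c: float) -> "DivisionParams":
        return cls(phi=360.0 * p_c)


@dataclass(frozen=True)
class DaughterOutcome:
    """Inherited content of the sector daughter for one realisation."""

    W: int
    M: int
    u: float
    orientation: float

    @property
    def N(self) -> int:
        return self.W + self.M

    @property
    def h(self) -> float | None:
        """Daughter heteroplasmy; None when no molecule was inherited."""
        return None if self.N == 0 else self.M / self.N


def normalized_vh(V_h: float, h_mother: float) -> float:
    """Normalised heteroplasmy variance V'(h) = V(h) / (h (1 - h))."""
    if not 0.0 < h_mother < 1.0:
        raise ValueError("normalisation undefined for h in {0, 1}")
    return V_h / (h_mother * (1.0 - h_mother))


def partition(
    popn: MtDNAPopulation,
    net: NetworkStructure | None,
    dv: DivisionParams,
    rng: np.random.Generator,
    orientation: float | None = None,
    both: bool = False,
):
    """Partition the cell along a randomly oriented sector of angle phi.

    A molecule is inherited iff its polar angle lies in
    [orientation, orientation + phi); a molecule exactly at the origin goes
    to the sector (measure-zero tie-break).  ``u`` is the fraction of network
    mass in the sector.  With ``both=True`` the complement daughter is
    returned as well (diagnostic mode for conservation checks).
    """
    if orientation is None:
        orientation = float(rng.uniform(0.0, _TWO_PI))
    phi_rad = math.radians(dv.phi)
    pos = popn.positions
    ang = np.mod(np.arctan2(pos[:, 1], pos[:, 0]) - orientation, _TWO_PI)
    at_origin = (pos[:, 0] == 0.0) & (pos[:, 1] == 0.0)
    inside = (ang < phi_rad) | at_origin

    def outcome(mask: np.ndarray, u: float, orient: float) -> DaughterOutcome:
        return DaughterOutcome(
            W=int(np.sum(mask & (popn.genotype == WILDTYPE))),
            M=int(np.sum(mask & (popn.genotype == MUTANT))),
            u=u,
            orientation=orient,
        )

    if net is not None and net.total_mass > 0:
        if dv.phi == 360.0:
            u = 1.0
        else:
            u = net.sector_mass(orientation, phi_rad) / net.total_mass
    else:
        u = float("nan")
    first = outcome(inside, u, orientation)
    if not both:
        return first
    u2 = 1.0 - u if u == u else u
    second = outcome(~inside, u2, (orientation + phi_rad) % _TWO_PI)
    return first, second


@dataclass(frozen=True)
class EnsembleSummary:
    """Monte-Carlo moments of daughter N, h and inherited network fraction U.

    Variances use the unbiased (n-1) estimator; h-moments are computed over
    realisations with N > 0 (``n_defined`` of ``n_reps``).  ``se_*`` fields
    are Monte-Carlo standard errors (the variance SEs use the fourth central
    moment of the replicate values).
    """

    n_reps: int
    n_defined: int
    E_N: float
    V_N: float
    E_h: float | None
    V_h: float | None
    Vp_h: float | None
    E_U: float
    V_U: float
    cov_WM: float
    se_E_N: float
    se_V_N: float
    se_E_h: float | None
    se_V_h: float | None
    se_Vp_h: float | None
    se_E_U: float
    relaxation_events: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _var_se(x: np.ndarray) -> float:
    """Standard error of the unbiased sample variance of ``x``."""
    n = len(x)
    if n < 4:
        return float("nan")
    v = np.var(x, ddof=1)
    m4 = np.mean((x - x.mean()) ** 4)
    return math.sqrt(max(m4 - (n - 3) / (n - 1) * v * v, 0.0) / n)


def summarize_outcomes(
    W: np.ndarray,
    M: np.ndarray,
    u: np.ndarray,
    h_mother: float,
    relaxation_events: int = 0,
) -> EnsembleSummary:
    """Reduce per-replicate outcomes to an :class:`EnsembleSummary`."""
    n = len(W)
    N = W + M
    defined = N > 0
    n_def = int(defined.sum())
    E_N = float(N.mean())
    V_N = float(np.var(N, ddof=1))
    u_ok = u[~np.isnan(u)]
    E_U = float(u_ok.mean()) if u_ok.size else float("nan")
    V_U = float(np.var(u_ok, ddof=1)) if u_ok.size > 1 else float("nan")
    cov = float(np.cov(W, M, ddof=1)[0, 1])

    if n_def >= 2:
        h = M[defined] / N[defined]
        E_h = float(h.mean())
        V_h = float(np.var(h, ddof=1))
        se_V_h = _var_se(h)
        se_E_h = math.sqrt(np.var(h, ddof=1) / n_def)
        if 0.0 < h_mother < 1.0:
            denom = h_mother * (1.0 - h_mother)
            Vp_h, se_Vp_h = V_h / denom, se_V_h / denom
        else:
            Vp_h = se_Vp_h = None
    else:
        E_h = V_h = Vp_h = se_E_h = se_V_h = se_Vp_h = None

    return EnsembleSummary(
        n_reps=n,
        n_defined=n_def,
        E_N=E_N,
        V_N=V_N,
        E_h=E_h,
        V_h=V_h,
        Vp_h=Vp_h,
        E_U=E_U,
        V_U=V_U,
        cov_WM=cov,
        se_E_N=math.sqrt(V_N / n),
        se_V_N=_var_se(N.astype(float)),
        se_E_h=se_E_h,
        se_V_h=se_V_h,
        se_Vp_h=se_Vp_h,
        se_E_U=math.sqrt(V_U / len(u_ok)) if u_ok.size > 1 else float("nan"),
        relaxation_events=relaxation_events,
    )


def run_ensemble(
    growth: GrowthParams,
    genetics: GeneticParams,
    placement: PlacementParams,
    diffusion: DiffusionParams | None,
    division: DivisionParams,
    n_reps: int,
    rng: np.random.Generator,
    geom: CellGeometry | None = None,
    network_mode: Literal["fresh", "fixed"] = "fresh",
    network: NetworkStructure | None = None,
    return_samples: bool = False,
):
    """Monte-Carlo ensemble of independent division realisations.

    Each replicate regrows the network (``network_mode="fresh"``), re-places
    the mtDNA population, optionally applies pre-division diffusion, and
    partitions once.  ``network_mode="fixed"`` grows a single network (or uses
    the one supplied) and reuses it across replicates — intended for variance
    decomposition experiments and for null-model runs with no networked
    molecules.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    geom = geom or CellGeometry()
    alloc: CountAllocation = allocate_counts(genetics)

    fixed_net = network
    if network_mode == "fixed" and fixed_net is None:
        fixed_net = grow_network(geom, growth, rng)

    W = np.empty(n_reps, dtype=np.int64)
    M = np.empty(n_reps, dtype=np.int64)
    u = np.empty(n_reps, dtype=float)
    orient = np.empty(n_reps, dtype=float)
    relaxations = 0
    for i in range(n_reps):
        net = fixed_net if network_mode == "fixed" else grow_network(geom, growth, rng)
        popn = place_population(net, alloc, placement, rng)
        relaxations += popn.relaxation_events
        if diffusion is not None and diffusion.lam > 0 and diffusion.n_steps > 0:
            popn = diffuse(popn, diffusion, rng)
        out = partition(popn, net, division, rng)
        W[i], M[i], u[i], orient[i] = out.W, out.M, out.u, out.orientation

    summary = summarize_outcomes(W, M, u, genetics.h, relaxations)
    if return_samples:
        import pandas as pd

        samples = pd.DataFrame(
            {
                "orientation": orient,
                "W": W,
                "M": M,
                "N": W + M,
                "h": np.where(W + M > 0, M / np.maximum(W + M, 1), np.nan),
                "u": u,
            }
        )
        return summary, samples
    return summary
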