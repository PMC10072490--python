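"""Analytic models of mtDNA inheritance at cell division.

Three nested statistical pictures of what a daughter cell inherits:

* **Binomial null** — no network: every molecule is inherited independently
  with probability ``p_c`` (the inherited cytoplasm fraction), giving
  ``V(N) = N0 p_c (1 - p_c)`` and normalised heteroplasmy variance
  ``V'(h) = (1 - p_c) / (p_c N0)``.

* **Random network placement** — the inherited network fraction is a
  beta-distributed variable ``U`` with mean ``p_c``; networked counts are
  binomial with the random probability ``U`` (hence beta-binomial), and the
  shared ``U`` couples wildtype and mutant inheritance:
  ``Cov(W_n, M_n) = w_n m_n V(U)``.

* **Repulsive placement** — evenly spaced molecules occupy discrete "spaces"
  along the network; the daughter's ``floor(u * spaces_total)`` spaces are
  filled by sampling molecules without replacement, so networked counts are
  hypergeometric with ``M_n`` determined by ``W_n`` (perfect negative
  coupling).  Deliberately a qualitative model of self-avoidance.

For each picture the moments of the daughter heteroplasmy ``h = M / (W + M)``
are available through several routes of increasing fidelity: closed forms,
first- and second-order delta-method (Taylor) expansions, an exhaustive sum
over the state variables with quadrature over ``U``, and — for tiny systems —
a brute-force enumeration oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats
from scipy.special import betaln, roots_jacobi

from .population import CountAllocation, GeneticParams, allocate_counts

__all__ = [
    "BetaNetworkParams",
    "ModelSpec",
    "ComponentMoments",
    "Prediction",
    "JointMoments",
    "binomial_null",
    "fit_beta",
    "moments_random",
    "moments_repulsive",
    "taylor_first_order",
    "taylor_second_order",
    "closed_form_copy_number",
    "closed_form_heteroplasmy",
    "exact_moments_sum",
    "brute_force_enumeration",
    "joint_moments",
    "spaces_literal",
    "spaces_geometric",
]


@dataclass(frozen=True)
class BetaNetworkParams:
    """Shape parameters of the inherited-network-fraction law U ~ Beta(a, b)."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta shape parameters must be positive")

    @property
    def E_U(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def V_U(self) -> float:
        s = self.alpha + self.beta
        return self.alpha * self.beta / (s * s * (s + 1.0))


def fit_beta(E_U: float, V_U: float) -> BetaNetworkParams:
    """Moment-match Beta(alpha, beta) to a mean and variance of U."""
    if not 0.0 < E_U < 1.0:
        raise ValueError("E_U must lie strictly in (0, 1)")
    bound = E_U * (1.0 - E_U)
    if not 0.0 < V_U < bound:
        raise ValueError(f"V_U must lie in (0, {bound}) for E_U = {E_U}")
    s = bound / V_U - 1.0
    return BetaNetworkParams(alpha=E_U * s, beta=(1.0 - E_U) * s)


def spaces_literal(l: float) -> int:
    """Total network 'spaces' reading floor(u/l) literally: floor(1/l)."""
    return int(math.floor(1.0 / l))


def spaces_geometric(l: float, mass_target: float = 50.0) -> int:
    """Total spaces from network capacity: length over spacing."""
    return int(math.floor(mass_target / l))


@dataclass(frozen=True)
class ModelSpec:
    """Full parameterisation of one analytic inheritance model."""

    N0: int
    h: float
    p: float
    q: float
    p_c: float = 0.5
    beta_params: BetaNetworkParams | None = None
    mode: Literal["null", "random", "repulsive"] = "random"
    spaces_total: int | None = None

    def __post_init__(self) -> None:
        GeneticParams(self.N0, self.h, self.p, self.q)  # validates ranges
        if not 0.0 < self.p_c < 1.0:
            raise ValueError("p_c must lie strictly in (0, 1)")
        if self.mode == "repulsive" and (self.spaces_total is None or self.spaces_total < 1):
            raise ValueError("repulsive mode requires spaces_total >= 1")

    @property
    def kappa(self) -> float:
        """Overall fraction of mtDNA in the network: p(1-h) + qh."""
        return self.p * (1.0 - self.h) + self.q * self.h

    @property
    def V_U(self) -> float:
        return 0.0 if self.beta_params is None else self.beta_params.V_U

    @property
    def E_U(self) -> float:
        return self.p_c if self.beta_params is None else self.beta_params.E_U

    def allocation(self) -> CountAllocation:
        return allocate_counts(GeneticParams(self.N0, self.h, self.p, self.q))


@dataclass(frozen=True)
class ComponentMoments:
    """Means/variances of the four compartment counts and their coupling.

    Components: networked/cytoplasmic wildtype (W_n, W_c) and mutant
    (M_n, M_c).  Cytoplasmic counts are independent of everything else, so
    the only covariance is Cov(W_n, M_n) through the shared inherited
    network fraction.
    """

    E_Wn: float
    V_Wn: float
    E_Wc: float
    V_Wc: float
    E_Mn: float
    V_Mn: float
    E_Mc: float
    V_Mc: float
    cov_WnMn: float

    @property
    def E_W(self) -> float:
        return self.E_Wn + self.E_Wc

    @property
    def E_M(self) -> float:
        return self.E_Mn + self.E_Mc

    @property
    def V_W(self) -> float:
        return self.V_Wn + self.V_Wc

    @property
    def V_M(self) -> float:
        return self.V_Mn + self.V_Mc

    @property
    def cov_WM(self) -> float:
        return self.cov_WnMn

    @property
    def V_N(self) -> float:
        """Copy-number variance assembled as V(W) + V(M) + 2 Cov(W, M)."""
        return self.V_W + self.V_M + 2.0 * self.cov_WM


@dataclass(frozen=True)
class Prediction:
    E_N: float
    V_N: float
    E_h: float | None
    V_h: float | None
    Vp_h: float | None
    method: str
    extras: dict = field(default_factory=dict)


def _normalize(V_h: float, h: float) -> float:
    return V_h / (h * (1.0 - h))


def binomial_null(N0: int, h: float, p_c: float) -> Prediction:
    """No-network null: both genotypes inherited Bin(count, p_c)."""
    if not 0.0 < h < 1.0:
        raise ValueError("binomial null requires 0 < h < 1")
    if not 0.0 < p_c < 1.0:
        raise ValueError("binomial null requires 0 < p_c < 1")
    if N0 < 1:
        raise ValueError("N0 must be >= 1")
    V_N = p_c * (1.0 - p_c) * N0
    Vp_h = (1.0 - p_c) / (p_c * N0)
    V_h = Vp_h * h * (1.0 - h)
    return Prediction(
        E_N=p_c * N0, V_N=V_N, E_h=h, V_h=V_h, Vp_h=Vp_h, method="closed_form"
    )


def _continuous_counts(spec: ModelSpec) -> tuple[float, float, float, float]:
    w_tot = (1.0 - spec.h) * spec.N0
    m_tot = spec.h * spec.N0
    return spec.p * w_tot, (1.0 - spec.p) * w_tot, spec.q * m_tot, (1.0 - spec.q) * m_tot


def moments_random(spec: ModelSpec) -> ComponentMoments:
    """Component moments under random (beta-binomial) network placement.

    Uses the continuous counts w_n = p(1-h)N0 etc. of the closed-form
    algebra; the networked variance is the beta-binomial law of total
    variance, and the shared U gives Cov(W_n, M_n) = w_n m_n V(U).  With no
    beta parameters U is degenerate at p_c and the binomial null re-emerges.
    """
    w_n, w_c, m_n, m_c = _continuous_counts(spec)
    E_U, V_U, p_c = spec.E_U, spec.V_U, spec.p_c
    bin_var = E_U * (1.0 - E_U)
    return ComponentMoments(
        E_Wn=w_n * E_U,
        V_Wn=w_n * bin_var + w_n * (w_n - 1.0) * V_U,
        E_Wc=w_c * p_c,
        V_Wc=w_c * p_c * (1.0 - p_c),
        E_Mn=m_n * E_U,
        V_Mn=m_n * bin_var + m_n * (m_n - 1.0) * V_U,
        E_Mc=m_c * p_c,
        V_Mc=m_c * p_c * (1.0 - p_c),
        cov_WnMn=w_n * m_n * V_U,
    )


def _beta_quadrature(bp: BetaNetworkParams | None, E_U: float, n: int):
    """Nodes/weights integrating smooth f against the Beta density on (0, 1).

    Gauss-Jacobi rule, exact for the beta weight (valid for shapes < 1 too);
    weights sum to one.  A degenerate U (no beta parameters) collapses to a
    single node at E_U.
    """
    if bp is None:
        return np.array([E_U]), np.array([1.0])
    a, b = bp.alpha, bp.beta
    x, w = roots_jacobi(n, b - 1.0, a - 1.0)
    u = 0.5 * (x + 1.0)
    logc = (1.0 - a - b) * math.log(2.0) - betaln(a, b)
    return u, w * math.exp(logc)


def _hypergeom_mean_var(d: int, w_n: int, m_n: int) -> tuple[float, float]:
    """Mean/variance of W_n ~ Hypergeometric(w_n + m_n, w_n, d)."""
    nn = w_n + m_n
    if nn == 0 or d == 0:
        return 0.0, 0.0
    f = w_n / nn
    if d >= nn or nn == 1:
        return float(w_n if d >= nn else d * f), 0.0
    return d * f, d * f * (1.0 - f) * (nn - d) / (nn - 1.0)


def _draw_count_masses(spec: ModelSpec, nn: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact law of d = min(floor(U * spaces_total), nn) under U ~ Beta(a, b).

    The repulsive model depends on U only through the integer draw count d,
    so the U-integral reduces to Beta CDF masses of the intervals
    [j/S, (j+1)/S) — no quadrature error.
    """
    S = spec.spaces_total
    if spec.beta_params is None:
        d = min(int(math.floor(spec.E_U * S)), nn)
        return np.array([d]), np.array([1.0])
    edges = np.arange(S + 1) / S
    cdf = stats.beta.cdf(edges, spec.beta_params.alpha, spec.beta_params.beta)
    interval_mass = np.diff(cdf)
    d_of_interval = np.minimum(np.arange(S), nn)
    masses = np.bincount(d_of_interval, weights=interval_mass, minlength=nn + 1)
    d_vals = np.flatnonzero(masses > 0)
    return d_vals, masses[d_vals]


def moments_repulsive(spec: ModelSpec, quad_nodes: int = 200) -> ComponentMoments:
    """Component moments of the hypergeometric (self-avoidance) model.

    Conditional on U = u, ``d(u) = min(floor(u * spaces_total), w_n + m_n)``
    networked spaces are filled without replacement, so
    ``Cov(W_n, M_n | u) = -V(W_n | u)``; marginal moments follow from the
    laws of total (co)variance, with U integrated exactly over the
    piecewise-constant draw count (``quad_nodes`` is accepted for interface
    symmetry but unused).
    """
    if spec.mode != "repulsive":
        raise ValueError("moments_repulsive requires mode='repulsive'")
    alloc = spec.allocation()
    w_n, m_n = alloc.w_n, alloc.m_n
    D, wgt = _draw_count_masses(spec, w_n + m_n)
    EW = np.empty(len(D))
    VW = np.empty(len(D))
    for i, d in enumerate(D):
        EW[i], VW[i] = _hypergeom_mean_var(int(d), w_n, m_n)
    EM = D - EW  # E[M_n | d] = d - E[W_n | d]
    mean_W = float(wgt @ EW)
    mean_M = float(wgt @ EM)
    V_Wn = float(wgt @ VW + wgt @ (EW - mean_W) ** 2)
    V_Mn = float(wgt @ VW + wgt @ (EM - mean_M) ** 2)
    cov = float(wgt @ (-VW) + wgt @ ((EW - mean_W) * (EM - mean_M)))
    p_c = spec.p_c
    return ComponentMoments(
        E_Wn=mean_W,
        V_Wn=V_Wn,
        E_Wc=alloc.w_c * p_c,
        V_Wc=alloc.w_c * p_c * (1.0 - p_c),
        E_Mn=mean_M,
        V_Mn=V_Mn,
        E_Mc=alloc.m_c * p_c,
        V_Mc=alloc.m_c * p_c * (1.0 - p_c),
        cov_WnMn=cov,
    )


def taylor_first_order(cm: ComponentMoments, h_mother: float) -> Prediction:
    """First-order delta-method variance of the ratio h = M / (W + M).

    ``V1(h) = h_M'^2 V(M) + h_W'^2 V(W) + 2 h_M' h_W' Cov(W, M)`` with the
    derivatives evaluated at the component means.  Note the covariance enters
    with a negative coefficient, so negative W-M coupling raises V(h).
    """
    E_W, E_M = cm.E_W, cm.E_M
    S = E_W + E_M
    if S <= 0:
        raise ValueError("expected total copy number must be positive")
    dh_dM = E_W / (S * S)
    dh_dW = -E_M / (S * S)
    V_h = (
        dh_dM * dh_dM * cm.V_M
        + dh_dW * dh_dW * cm.V_W
        + 2.0 * dh_dM * dh_dW * cm.cov_WM
    )
    E_h = E_M / S
    Vp = _normalize(V_h, h_mother) if 0.0 < h_mother < 1.0 else None
    return Prediction(
        E_N=S, V_N=cm.V_N, E_h=E_h, V_h=V_h, Vp_h=Vp, method="taylor1",
        extras={"dh_dW": dh_dW, "dh_dM": dh_dM},
    )


def closed_form_copy_number(spec: ModelSpec) -> float:
    """V(N) = N0 p_c (1 - p_c) + kappa N0 (kappa N0 - 1) V(U)."""
    K = spec.kappa * spec.N0
    return spec.N0 * spec.p_c * (1.0 - spec.p_c) + K * (K - 1.0) * spec.V_U


def closed_form_heteroplasmy(spec: ModelSpec) -> float:
    """Normalised first-order heteroplasmy variance for random placement.

    ``V1'(h) = (1-p_c)/(p_c N0)
             + (V(U)/p_c^2) (h(1-h)(p-q)^2 - (p h + q (1-h))/N0)``.
    Reduces to the binomial null for V(U) = 0 and, at (p, q) = (1, 0),
    to ``1/N0 + 4 V(U) (h(1-h) - h/N0)`` for symmetric division.
    """
    if not 0.0 < spec.h < 1.0:
        raise ValueError("normalised heteroplasmy variance requires 0 < h < 1")
    h, p, q, N0, p_c = spec.h, spec.p, spec.q, spec.N0, spec.p_c
    null = (1.0 - p_c) / (p_c * N0)
    bracket = h * (1.0 - h) * (p - q) ** 2 - (p * h + q * (1.0 - h)) / N0
    return null + spec.V_U / (p_c * p_c) * bracket


# ---------------------------------------------------------------------------
# exhaustive sums over state variables
# ---------------------------------------------------------------------------


def _pmf_binom(n: int, p: float) -> np.ndarray:
    return stats.binom.pmf(np.arange(n + 1), n, p)


class _MomentAccumulator:
    """Accumulates E(N), E(N^2), E(h 1{N>0}), E(h^2 1{N>0}) and P(N = 0)."""

    def __init__(self) -> None:
        self.EN = self.EN2 = self.h1 = self.h2 = self.p0 = 0.0

    def add(self, w: float, EN: float, EN2: float, h1: float, h2: float, p0: float):
        self.EN += w * EN
        self.EN2 += w * EN2
        self.h1 += w * h1
        self.h2 += w * h2
        self.p0 += w * p0

    def prediction(self, h_mother: float, method: str, **extras) -> Prediction:
        mass = 1.0 - self.p0
        if mass <= 0:
            E_h = V_h = Vp = None
        else:
            E_h = self.h1 / mass
            V_h = max(self.h2 / mass - E_h * E_h, 0.0)
            Vp = _normalize(V_h, h_mother) if 0.0 < h_mother < 1.0 else None
        V_N = max(self.EN2 - self.EN * self.EN, 0.0)
        return Prediction(
            E_N=self.EN, V_N=V_N, E_h=E_h, V_h=V_h, Vp_h=Vp, method=method,
            extras={"p_zero": self.p0, **extras},
        )


def _h_grids(w_tot: int, m_tot: int) -> tuple[np.ndarray, np.ndarray]:
    Wv = np.arange(w_tot + 1)[:, None]
    Mv = np.arange(m_tot + 1)[None, :]
    Nv = Wv + Mv
    with np.errstate(divide="ignore", invalid="ignore"):
        H = np.where(Nv > 0, Mv / np.maximum(Nv, 1), 0.0)
    return H, H * H


def _exact_sum_once(spec: ModelSpec, quad_nodes: int) -> Prediction:
    alloc = spec.allocation()
    w_n, w_c, m_n, m_c = alloc
    w_tot, m_tot = w_n + w_c, m_n + m_c
    p_c = spec.p_c
    acc = _MomentAccumulator()

    if spec.mode == "null":
        pW = _pmf_binom(w_tot, p_c)
        pM = _pmf_binom(m_tot, p_c)
        H, H2 = _h_grids(w_tot, m_tot)
        EW = w_tot * p_c
        EM = m_tot * p_c
        EN2 = (
            w_tot * p_c * (1 - p_c) + EW**2
            + 2 * EW * EM
            + m_tot * p_c * (1 - p_c) + EM**2
        )
        acc.add(1.0, EW + EM, EN2, pW @ H @ pM, pW @ H2 @ pM, pW[0] * pM[0])
        return acc.prediction(spec.h, "exact_sum")

    pWc = _pmf_binom(w_c, p_c)
    pMc = _pmf_binom(m_c, p_c)
    H, H2 = _h_grids(w_tot, m_tot)

    if spec.mode == "random":
        u_nodes, wgt = _beta_quadrature(spec.beta_params, spec.E_U, quad_nodes)
        Wvals = np.arange(w_tot + 1)
        Mvals = np.arange(m_tot + 1)
        for u, w in zip(u_nodes, wgt):
            pW = np.convolve(_pmf_binom(w_n, float(u)), pWc)
            pM = np.convolve(_pmf_binom(m_n, float(u)), pMc)
            EW = float(pW @ Wvals)
            EW2 = float(pW @ Wvals**2)
            EM = float(pM @ Mvals)
            EM2 = float(pM @ Mvals**2)
            acc.add(
                float(w),
                EW + EM,
                EW2 + 2 * EW * EM + EM2,
                float(pW @ H @ pM),
                float(pW @ H2 @ pM),
                float(pW[0] * pM[0]),
            )
    elif spec.mode == "repulsive":
        nn = w_n + m_n
        nc = w_c + m_c
        d_vals, d_wgt = _draw_count_masses(spec, nn)
        for d, w in zip(d_vals, d_wgt):
            d = int(d)
            lo = max(0, d - m_n)
            hi = min(d, w_n)
            ks = np.arange(lo, hi + 1)
            pWn = np.ones(1) if nn == 0 else stats.hypergeom.pmf(ks, nn, w_n, d)
            h1 = h2 = 0.0
            for k, pk in zip(ks, pWn):
                Hs = H[k : k + w_c + 1, d - k : d - k + m_c + 1]
                H2s = H2[k : k + w_c + 1, d - k : d - k + m_c + 1]
                h1 += pk * float(pWc @ Hs @ pMc)
                h2 += pk * float(pWc @ H2s @ pMc)
            EN = d + nc * p_c
            VN = nc * p_c * (1 - p_c)
            p0 = (pWc[0] * pMc[0]) if d == 0 else 0.0
            acc.add(float(w), EN, VN + EN * EN, h1, h2, float(p0))
    else:
        raise ValueError(f"unknown mode {spec.mode!r}")
    return acc.prediction(spec.h, "exact_sum")


def exact_moments_sum(
    spec: ModelSpec, quad_nodes: int = 200, check_convergence: bool = True
) -> Prediction:
    """Moments of N and h by exhaustively summing over the state variables.

    For each quadrature node u of the inherited-network-fraction law, the
    conditional distributions of W = W_n + W_c and M = M_n + M_c are built by
    discrete convolution (the four-fold sum collapses because W and M are
    conditionally independent given U, except in the repulsive model where
    M_n = d - W_n is handled explicitly) and the moment functionals are summed
    over the (W, M) grid.  h-moments exclude the (W, M) = (0, 0) atom, whose
    mass is reported in ``extras['p_zero']``.
    """
    if spec.N0 > 5000:
        raise ValueError("exact sum limited to N0 <= 5000")
    if quad_nodes < 32:
        raise ValueError("quad_nodes must be >= 32")
    result = _exact_sum_once(spec, quad_nodes)
    if check_convergence and spec.beta_params is not None and spec.mode == "random":
        refined = _exact_sum_once(spec, 2 * quad_nodes)
        rel = 0.0
        for a, b in ((result.V_N, refined.V_N), (result.V_h, refined.V_h)):
            if a is not None and b is not None and abs(b) > 0:
                rel = max(rel, abs(a - b) / max(abs(b), 1e-300))
        if rel > 1e-8:
            warnings.warn(
                f"quadrature not converged (relative change {rel:.2e} on node doubling)",
                RuntimeWarning,
                stacklevel=2,
            )
        result = refined
    return result


def brute_force_enumeration(spec: ModelSpec, quad_nodes: int = 200) -> Prediction:
    """Enumerate every (W_n, W_c, M_n, M_c) outcome with its probability.

    Independent oracle for :func:`exact_moments_sum`: no convolution
    shortcuts, every joint outcome is visited.  Refuses N0 > 12.
    """
    if spec.N0 > 12:
        raise ValueError("brute-force enumeration limited to N0 <= 12")
    alloc = spec.allocation()
    w_n, w_c, m_n, m_c = alloc
    p_c = spec.p_c
    acc = _MomentAccumulator()
    pWc = _pmf_binom(w_c, p_c)
    pMc = _pmf_binom(m_c, p_c)

    if spec.mode in ("null", "random"):
        if spec.mode == "null":
            u_nodes, wgt = np.array([0.0]), np.array([1.0])
        else:
            u_nodes, wgt = _beta_quadrature(spec.beta_params, spec.E_U, quad_nodes)
        wn_v = np.arange(w_n + 1)
        wc_v = np.arange(w_c + 1)
        mn_v = np.arange(m_n + 1)
        mc_v = np.arange(m_c + 1)
        Ng = (
            wn_v[:, None, None, None]
            + wc_v[None, :, None, None]
            + mn_v[None, None, :, None]
            + mc_v[None, None, None, :]
        ).astype(float)
        Mg = (mn_v[None, None, :, None] + mc_v[None, None, None, :]).astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            Hg = np.where(Ng > 0, Mg / np.maximum(Ng, 1.0), 0.0)
        for u, w in zip(u_nodes, wgt):
            pu = p_c if spec.mode == "null" else float(u)
            P = np.einsum(
                "i,j,k,l->ijkl",
                _pmf_binom(w_n, pu),
                pWc,
                _pmf_binom(m_n, pu),
                pMc,
            )
            acc.add(
                float(w),
                float((P * Ng).sum()),
                float((P * Ng * Ng).sum()),
                float((P * Hg).sum()),
                float((P * Hg * Hg).sum()),
                float(P[0, 0, 0, 0]),
            )
    elif spec.mode == "repulsive":
        nn = w_n + m_n
        wc_v = np.arange(w_c + 1)
        mc_v = np.arange(m_c + 1)
        d_vals, d_wgt = _draw_count_masses(spec, nn)
        for d, w in zip(d_vals, d_wgt):
            d = int(d)
            lo, hi = max(0, d - m_n), min(d, w_n)
            for k in range(lo, hi + 1):
                pk = 1.0 if nn == 0 else float(stats.hypergeom.pmf(k, nn, w_n, d))
                P = np.einsum("j,l->jl", pWc, pMc) * pk
                Wg = (k + wc_v)[:, None].astype(float)
                Mg = (d - k + mc_v)[None, :].astype(float)
                Ng = Wg + Mg
                with np.errstate(divide="ignore", invalid="ignore"):
                    Hg = np.where(Ng > 0, Mg / np.maximum(Ng, 1.0), 0.0)
                acc.add(
                    float(w),
                    float((P * Ng).sum()),
                    float((P * Ng * Ng).sum()),
                    float((P * Hg).sum()),
                    float((P * Hg * Hg).sum()),
                    float(P[0, 0]) if d == 0 and k == 0 else 0.0,
                )
    else:
        raise ValueError(f"unknown mode {spec.mode!r}")
    return acc.prediction(spec.h, "enumeration")


# ---------------------------------------------------------------------------
# higher moments and the second-order expansion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JointMoments:
    """Central moments mu_ab = E[(W - E W)^a (M - E M)^b] up to a + b = order."""

    E_W: float
    E_M: float
    central: dict

    def mu(self, a: int, b: int) -> float:
        return self.central[(a, b)]


def _vector_raw_moments(pmf: np.ndarray, order: int) -> np.ndarray:
    vals = np.arange(len(pmf), dtype=float)
    return np.array([pmf @ vals**a for a in range(order + 1)])


def joint_moments(spec: ModelSpec, order: int = 4, quad_nodes: int = 200) -> JointMoments:
    """Exact joint raw-then-central moments of (W, M) up to ``order``.

    Per quadrature node the conditional moments are computed from the exact
    conditional distributions; mixing over U and centring gives the joint
    central moments needed by the second-order expansion.
    """
    alloc = spec.allocation()
    w_n, w_c, m_n, m_c = alloc
    p_c = spec.p_c
    pWc = _pmf_binom(w_c, p_c)
    pMc = _pmf_binom(m_c, p_c)
    raw = {(a, b): 0.0 for a in range(order + 1) for b in range(order + 1) if a + b <= order}

    if spec.mode in ("null", "random"):
        if spec.mode == "null":
            u_nodes, wgt = np.array([p_c]), np.array([1.0])
        else:
            u_nodes, wgt = _beta_quadrature(spec.beta_params, spec.E_U, quad_nodes)
        for u, w in zip(u_nodes, wgt):
            pu = p_c if spec.mode == "null" else float(u)
            mW = _vector_raw_moments(np.convolve(_pmf_binom(w_n, pu), pWc), order)
            mM = _vector_raw_moments(np.convolve(_pmf_binom(m_n, pu), pMc), order)
            for (a, b) in raw:
                raw[(a, b)] += float(w) * mW[a] * mM[b]
    else:  # repulsive: W = k + Wc, M = (d - k) + Mc with k hypergeometric
        nn = w_n + m_n
        wc_v = np.arange(w_c + 1, dtype=float)
        mc_v = np.arange(m_c + 1, dtype=float)
        d_vals, d_wgt = _draw_count_masses(spec, nn)
        for d, w in zip(d_vals, d_wgt):
            d = int(d)
            lo, hi = max(0, d - m_n), min(d, w_n)
            ks = np.arange(lo, hi + 1)
            pk = np.ones(1) if nn == 0 else stats.hypergeom.pmf(ks, nn, w_n, d)
            for k, pkk in zip(ks, pk):
                mW = np.array([pWc @ (k + wc_v) ** a for a in range(order + 1)])
                mM = np.array([pMc @ (d - k + mc_v) ** b for b in range(order + 1)])
                for (a, b) in raw:
                    raw[(a, b)] += float(w) * float(pkk) * mW[a] * mM[b]

    E_W, E_M = raw[(1, 0)], raw[(0, 1)]
    central = {}
    for (a, b) in raw:
        tot = 0.0
        for i in range(a + 1):
            for j in range(b + 1):
                tot += (
                    math.comb(a, i)
                    * math.comb(b, j)
                    * (-E_W) ** (a - i)
                    * (-E_M) ** (b - j)
                    * raw[(i, j)]
                )
        central[(a, b)] = tot
    return JointMoments(E_W=E_W, E_M=E_M, central=central)


def taylor_second_order(jm: JointMoments, h_mother: float) -> Prediction:
    """Second-order delta-method estimate of E(h) and V(h).

    Generic multivariate expansion of h = M / (W + M) about the means, using
    joint central moments of (W, M) up to fourth order.  An approximation —
    its residual against :func:`exact_moments_sum` is a property of the
    expansion, not assumed to vanish.
    """
    muW, muM = jm.E_W, jm.E_M
    S = muW + muM
    if S <= 0:
        raise ValueError("expected total copy number must be positive")
    g1 = -muM / S**2  # d h / d W
    g2 = muW / S**2  # d h / d M
    H11 = 2.0 * muM / S**3
    H22 = -2.0 * muW / S**3
    H12 = (muM - muW) / S**3

    mu = jm.mu
    trHC = H11 * mu(2, 0) + 2.0 * H12 * mu(1, 1) + H22 * mu(0, 2)
    E_h = muM / S + 0.5 * trHC

    term1 = g1 * g1 * mu(2, 0) + 2.0 * g1 * g2 * mu(1, 1) + g2 * g2 * mu(0, 2)
    term2 = g1 * (H11 * mu(3, 0) + 2.0 * H12 * mu(2, 1) + H22 * mu(1, 2)) + g2 * (
        H11 * mu(2, 1) + 2.0 * H12 * mu(1, 2) + H22 * mu(0, 3)
    )
    quad = (
        H11 * H11 * mu(4, 0)
        + 4.0 * H11 * H12 * mu(3, 1)
        + (2.0 * H11 * H22 + 4.0 * H12 * H12) * mu(2, 2)
        + 4.0 * H12 * H22 * mu(1, 3)
        + H22 * H22 * mu(0, 4)
    )
    V_h = term1 + term2 + 0.25 * (quad - trHC * trHC)
    V_N = mu(2, 0) + mu(0, 2) + 2.0 * mu(1, 1)
    Vp = _normalize(V_h, h_mother) if 0.0 < h_mother < 1.0 else None
    return Prediction(
        E_N=S, V_N=V_N, E_h=E_h, V_h=V_h, Vp_h=Vp, method="taylor2"
    )
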