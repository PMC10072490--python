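"""Random mitochondrial networks in a circular cell.

The cell is the unit disc (all lengths in units of the cell radius ``r``).
A network is grown from ``s`` evenly-spaced seed points on the perimeter by an
elongation-and-branching process: each active tip elongates deterministically
by ``e`` per time step and spawns a new tip with probability ``1 - exp(-k)``
per step (Poissonian branching at rate ``k``).  Tips start on the perimeter
heading radially inward, grow in straight lines, and die when they hit the
cell boundary (final increments clipped to the circle).  Growth stops once a
prescribed total network length (``mass_target``, default ``50`` cell radii)
has been laid down, the last elongation increment being trimmed so the mass
is exact; if every tip dies first, the perimeter is re-seeded and growth
continues.

Small seed counts give heterogeneous networks (dense lobes, empty regions);
large seed counts give homogeneous, evenly spread networks.  This tunable
heterogeneity is the only role of the growth process — it is a generator of
plausible network geometries, not a biophysical model of fission/fusion.

The module also measures network mass inside angular sectors (the quantity
partitioned at cell division) and samples points uniformly by arc length
(used to place mtDNA molecules on the network).

Because ensembles regrow a fresh network for every division replicate, the
growth loop is the hot path; it is compiled with numba when available, with
an equivalent pure-NumPy event-driven implementation as fallback.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False

    def njit(*a, **k):  # type: ignore
        def wrap(fn):
            return fn

        return wrap


__all__ = [
    "CellGeometry",
    "GrowthParams",
    "NetworkStructure",
    "NetworkGrowthError",
    "generate_seed_points",
    "grow_network",
    "sample_network_point",
    "mass_in_sector",
    "make_fixture",
    "write_network",
    "read_network",
]

_TWO_PI = 2.0 * math.pi


class NetworkGrowthError(RuntimeError):
    """Raised when network generation cannot reach its mass target."""


@dataclass(frozen=True)
class CellGeometry:
    """Circular 2D cell of unit radius.

    ``physical_radius_um`` and ``tubule_width_um`` are reporting-only
    conversions to physical units (defaults: a 40 um fibroblast-like cell
    with 0.4 um mitochondrial tubules); the simulation itself is
    dimensionless.
    """

    radius: float = 1.0
    physical_radius_um: float = 40.0
    tubule_width_um: float = 0.4

    def __post_init__(self) -> None:
        if self.radius != 1.0:
            raise ValueError("simulation radius is fixed at 1 (lengths are in units of r)")

    def mitochondrial_area_fraction(self, mass_target: float) -> float:
        """Fraction of the cell area occupied by network tubules.

        A network of total length ``mass_target`` (in cell radii) with
        tubule width ``w`` covers ``mass_target * r * w`` of the cell area
        ``pi * r**2``; at the defaults this is about 16%.
        """
        length_um = mass_target * self.physical_radius_um
        return (length_um * self.tubule_width_um) / (math.pi * self.physical_radius_um**2)

    def spacing_um(self, l: float) -> float:
        """Physical inter-nucleoid spacing for exclusion radius ``l`` (cell radii)."""
        return l * self.physical_radius_um


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the elongation-and-branching growth process.

    e : elongation increment per time step (cell radii).
    k : branching rate per active tip per time step.
    s : number of evenly-spaced perimeter seed points.
    mass_target : total network length to lay down (cell radii).
    branch_angle_range : half-width of the uniform branch deviation angle (rad).
    max_reseeds : cap on perimeter re-seeding rounds before giving up.
    """

    s: int
    e: float = 0.01
    k: float = 0.02
    mass_target: float = 50.0
    branch_angle_range: float = math.pi / 2.0
    max_reseeds: int = 200

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValueError(f"seed count s must be >= 1, got {self.s}")
        if self.e <= 0:
            raise ValueError("elongation increment e must be positive")
        if self.k < 0:
            raise ValueError("branching rate k must be non-negative")
        if self.mass_target <= 0:
            raise ValueError("mass_target must be positive")


class _SectorIndex:
    """Arc-length mass as a function of polar angle, at fixed resolution.

    Every straight edge is subdivided into pieces of length <= resolution;
    pieces are binned by the polar angle of their midpoint.  Mass in an
    arbitrary sector is then two binary searches over the sorted midpoint
    angles, with O(resolution) error per sector-boundary crossing.
    """

    def __init__(
        self, starts: np.ndarray, vecs: np.ndarray, lens: np.ndarray, resolution: float
    ) -> None:
        if len(lens):
            n = np.maximum(1, np.ceil(lens / resolution).astype(np.int64))
            total = int(n.sum())
            edge_of = np.repeat(np.arange(len(lens)), n)
            offset = np.arange(total) - np.repeat(np.cumsum(n) - n, n)
            t = (offset + 0.5) / n[edge_of]
            mid = starts[edge_of] + t[:, None] * vecs[edge_of]
            piece_len = (lens / n)[edge_of]
            ang = np.mod(np.arctan2(mid[:, 1], mid[:, 0]), _TWO_PI)
            order = np.argsort(ang)
            self._ang = ang[order]
            self._cum = np.concatenate([[0.0], np.cumsum(piece_len[order])])
        else:
            self._ang = np.empty(0)
            self._cum = np.zeros(1)
        self.total = float(self._cum[-1])

    def _cum_at(self, theta: float) -> float:
        return float(self._cum[np.searchsorted(self._ang, theta, side="left")])

    def mass(self, sector_start: float, sector_angle: float) -> float:
        a = sector_start % _TWO_PI
        b = a + sector_angle
        if b <= _TWO_PI:
            return self._cum_at(b) - self._cum_at(a)
        return (self.total - self._cum_at(a)) + self._cum_at(b - _TWO_PI)


class NetworkStructure:
    """A piecewise-linear network embedded in the unit disc.

    Stored internally as a flat array of straight edges; ``segments``
    exposes the polyline view (a list of ``(n, 2)`` vertex arrays).
    ``total_mass`` is the summed arc length in cell radii.
    """

    def __init__(
        self,
        edges: np.ndarray,
        seed_angles: np.ndarray | None = None,
        reseed_count: int = 0,
        resolution: float = 0.01,
    ) -> None:
        edges = np.asarray(edges, dtype=float).reshape(-1, 4)
        vecs = edges[:, 2:] - edges[:, :2]
        lens = np.hypot(vecs[:, 0], vecs[:, 1])
        keep = lens > 1e-12
        self._starts = edges[keep, :2]
        self._vecs = vecs[keep]
        self._lens = lens[keep]
        self.total_mass = float(self._lens.sum())
        self.seed_angles = np.empty(0) if seed_angles is None else np.asarray(seed_angles)
        self.reseed_count = int(reseed_count)
        self.resolution = float(resolution)
        self._cum: np.ndarray | None = None
        self._index: _SectorIndex | None = None
        self._segments: list[np.ndarray] | None = None

    @classmethod
    def from_segments(cls, segments: Sequence[np.ndarray], **kw) -> "NetworkStructure":
        rows = []
        for seg in segments:
            seg = np.asarray(seg, dtype=float)
            rows.append(np.hstack([seg[:-1], seg[1:]]))
        edges = np.concatenate(rows) if rows else np.empty((0, 4))
        return cls(edges, **kw)

    @property
    def segments(self) -> list[np.ndarray]:
        if self._segments is None:
            self._segments = [
                np.vstack([a, a + v]) for a, v in zip(self._starts, self._vecs)
            ]
        return self._segments

    def flattened_edges(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(starts, vectors, lengths, cumulative lengths) of all straight edges."""
        if self._cum is None:
            self._cum = np.cumsum(self._lens)
        return self._starts, self._vecs, self._lens, self._cum

    def sector_index(self) -> _SectorIndex:
        if self._index is None:
            self._index = _SectorIndex(self._starts, self._vecs, self._lens, self.resolution)
        return self._index

    def sector_mass(self, sector_start: float, sector_angle: float) -> float:
        """Network mass in [sector_start, sector_start + sector_angle).

        Same subdivision rule as :class:`_SectorIndex`; single queries use a
        compiled one-pass scan, repeated queries the sorted index.
        """
        if self._index is None and _HAVE_NUMBA:
            return float(
                _sector_mass_kernel(
                    self._starts, self._vecs, self._lens,
                    self.resolution, sector_start, sector_angle,
                )
            )
        return self.sector_index().mass(sector_start, sector_angle)


def generate_seed_points(s: int, rng: np.random.Generator) -> np.ndarray:
    """``s`` evenly-spaced perimeter angles with a uniformly random offset."""
    if s < 1:
        raise ValueError(f"seed count must be >= 1, got {s}")
    theta0 = rng.uniform(0.0, _TWO_PI)
    return np.mod(theta0 + _TWO_PI * np.arange(s) / s, _TWO_PI)


@njit(cache=True)
def _grow_kernel(seed, s, e, p_branch, target, branch_range, max_reseeds):  # pragma: no cover
    """Event-driven growth loop (compiled): returns (edges, seed_angles, reseeds, status).

    Tips advance whole inter-event intervals at once: branch waiting times
    are geometric in integer steps (success probability ``p_branch``),
    boundary deaths and the mass-target cut happen at fractional step times.
    status: 0 ok, 1 reseed limit exceeded, 2 capacity exceeded.
    """
    np.random.seed(seed)
    TIP_CAP = 8192
    SEG_CAP = 1 << 17
    INF = 1e18
    two_pi = 2.0 * np.pi
    px = np.empty(TIP_CAP)
    py = np.empty(TIP_CAP)
    dx = np.empty(TIP_CAP)
    dy = np.empty(TIP_CAP)
    sx = np.empty(TIP_CAP)
    sy = np.empty(TIP_CAP)
    td = np.empty(TIP_CAP)
    tb = np.empty(TIP_CAP)
    seg = np.empty((SEG_CAP, 4))
    angles = np.empty(s * (max_reseeds + 2))
    n_ang = 0
    nseg = 0
    n = 0
    mass = 0.0
    reseeds = -1
    status = 0
    eps = 1e-12
    logq = np.log1p(-p_branch) if p_branch > 0.0 else -1.0

    while True:
        if n == 0:
            if target - mass <= eps:
                break
            reseeds += 1
            if reseeds > max_reseeds:
                status = 1
                break
            theta0 = np.random.uniform(0.0, two_pi)
            for i in range(s):
                ang = (theta0 + two_pi * i / s) % two_pi
                angles[n_ang] = ang
                n_ang += 1
                cx = np.cos(ang)
                cy = np.sin(ang)
                px[n] = cx
                py[n] = cy
                dx[n] = -cx
                dy[n] = -cy
                sx[n] = cx
                sy[n] = cy
                td[n] = 2.0 / e  # radial chord through the centre has length 2
                if p_branch > 0.0:
                    tb[n] = np.ceil(np.log1p(-np.random.random()) / logq)
                else:
                    tb[n] = INF
                n += 1
            continue

        tmin = INF
        for i in range(n):
            if td[i] < tmin:
                tmin = td[i]
            if tb[i] < tmin:
                tmin = tb[i]
        dt_mass = (target - mass) / (e * n)
        if dt_mass <= tmin:
            for i in range(n):
                px[i] += dx[i] * e * dt_mass
                py[i] += dy[i] * e * dt_mass
                seg[nseg, 0] = sx[i]
                seg[nseg, 1] = sy[i]
                seg[nseg, 2] = px[i]
                seg[nseg, 3] = py[i]
                nseg += 1
            mass = target
            break

        dt = tmin
        mass += e * dt * n
        for i in range(n):
            px[i] += dx[i] * e * dt
            py[i] += dy[i] * e * dt
            td[i] -= dt
            tb[i] -= dt

        i = n - 1
        while i >= 0:  # deaths: clip to the circle, swap-remove
            if td[i] <= eps:
                norm = np.sqrt(px[i] * px[i] + py[i] * py[i])
                seg[nseg, 0] = sx[i]
                seg[nseg, 1] = sy[i]
                seg[nseg, 2] = px[i] / norm
                seg[nseg, 3] = py[i] / norm
                nseg += 1
                n -= 1
                px[i] = px[n]
                py[i] = py[n]
                dx[i] = dx[n]
                dy[i] = dy[n]
                sx[i] = sx[n]
                sy[i] = sy[n]
                td[i] = td[n]
                tb[i] = tb[n]
            i -= 1

        n0 = n
        for i in range(n0):
            if tb[i] <= eps:
                if n >= TIP_CAP or nseg >= SEG_CAP - TIP_CAP:
                    status = 2
                    break
                delta = np.random.uniform(-branch_range, branch_range)
                cd = np.cos(delta)
                sd = np.sin(delta)
                ndx = dx[i] * cd - dy[i] * sd
                ndy = dx[i] * sd + dy[i] * cd
                px[n] = px[i]
                py[n] = py[i]
                dx[n] = ndx
                dy[n] = ndy
                sx[n] = px[i]
                sy[n] = py[i]
                b = -(px[i] * ndx + py[i] * ndy)
                c = px[i] * px[i] + py[i] * py[i] - 1.0
                disc = b * b - c
                if disc < 0.0:
                    disc = 0.0
                td[n] = (b + np.sqrt(disc)) / e
                tb[n] = np.ceil(np.log1p(-np.random.random()) / logq)
                tb[i] = np.ceil(np.log1p(-np.random.random()) / logq)
                n += 1
        if status == 2:
            break

    return seg[:nseg].copy(), angles[:n_ang].copy(), reseeds, status


@njit(cache=True)
def _sector_mass_kernel(starts, vecs, lens, resolution, a, phi):  # pragma: no cover
    """One-pass sector mass: subdivide each edge, classify piece midpoints."""
    two_pi = 2.0 * np.pi
    a = a % two_pi
    total = 0.0
    for i in range(len(lens)):
        n = int(np.ceil(lens[i] / resolution))
        if n < 1:
            n = 1
        piece = lens[i] / n
        for j in range(n):
            t = (j + 0.5) / n
            mx = starts[i, 0] + t * vecs[i, 0]
            my = starts[i, 1] + t * vecs[i, 1]
            rel = (np.arctan2(my, mx) - a) % two_pi
            if rel < phi:
                total += piece
    return total


def _ray_exit_distance(pos: np.ndarray, dirn: np.ndarray) -> np.ndarray:
    """Distance from interior points ``pos`` to the unit circle along ``dirn``."""
    b = np.einsum("ij,ij->i", pos, dirn)
    c = np.einsum("ij,ij->i", pos, pos) - 1.0
    disc = np.maximum(b * b - c, 0.0)
    return -b + np.sqrt(disc)


def _grow_python(gp: GrowthParams, rng: np.random.Generator):
    """NumPy fallback of :func:`_grow_kernel` (same events, Generator RNG)."""
    e, target = gp.e, gp.mass_target
    p_branch = -math.expm1(-gp.k)

    def branch_wait(n: int) -> np.ndarray:
        if p_branch <= 0.0:
            return np.full(n, np.inf)
        return rng.geometric(p_branch, size=n).astype(float)

    seed_angle_sets: list[np.ndarray] = []
    rows: list[np.ndarray] = []

    def seed_tips():
        ang = generate_seed_points(gp.s, rng)
        seed_angle_sets.append(ang)
        pos = np.column_stack([np.cos(ang), np.sin(ang)])
        return pos, -pos.copy(), pos.copy()

    pos, dirn, start = seed_tips()
    td = _ray_exit_distance(pos, dirn) / e
    tb = branch_wait(len(pos))
    mass, reseeds, eps = 0.0, 0, 1e-12

    while True:
        n = len(pos)
        if n == 0:
            if target - mass <= eps:
                break
            reseeds += 1
            if reseeds > gp.max_reseeds:
                raise NetworkGrowthError(
                    f"mass target {target} not reached after {gp.max_reseeds} re-seeds"
                )
            pos, dirn, start = seed_tips()
            td = _ray_exit_distance(pos, dirn) / e
            tb = branch_wait(len(pos))
            continue

        dt_mass = (target - mass) / (e * n)
        dt_evt = min(td.min(), tb.min())
        if dt_mass <= dt_evt:
            pos = pos + dirn * (e * dt_mass)
            rows.append(np.hstack([start, pos]))
            break

        pos = pos + dirn * (e * dt_evt)
        mass += e * dt_evt * n
        td -= dt_evt
        tb -= dt_evt

        died = td <= eps
        if died.any():
            dead = pos[died] / np.hypot(pos[died, 0], pos[died, 1])[:, None]
            rows.append(np.hstack([start[died], dead]))
            keep = ~died
            pos, dirn, start, td, tb = pos[keep], dirn[keep], start[keep], td[keep], tb[keep]
            if len(pos) == 0:
                continue

        branching = np.flatnonzero(tb <= eps)
        if branching.size:
            delta = rng.uniform(-gp.branch_angle_range, gp.branch_angle_range, branching.size)
            cd, sd = np.cos(delta), np.sin(delta)
            pd = dirn[branching]
            child_dir = np.column_stack(
                [pd[:, 0] * cd - pd[:, 1] * sd, pd[:, 0] * sd + pd[:, 1] * cd]
            )
            child_pos = pos[branching].copy()
            tb[branching] = branch_wait(branching.size)
            pos = np.concatenate([pos, child_pos])
            dirn = np.concatenate([dirn, child_dir])
            start = np.concatenate([start, child_pos.copy()])
            td = np.concatenate([td, _ray_exit_distance(child_pos, child_dir) / e])
            tb = np.concatenate([tb, branch_wait(branching.size)])

    edges = np.concatenate(rows) if rows else np.empty((0, 4))
    return edges, np.concatenate(seed_angle_sets), reseeds


def grow_network(
    geom: CellGeometry, gp: GrowthParams, rng: np.random.Generator
) -> NetworkStructure:
    """Grow a random network until exactly ``gp.mass_target`` length exists."""
    p_branch = -math.expm1(-gp.k)
    if _HAVE_NUMBA:
        seed = int(rng.integers(0, 2**31 - 1))
        edges, angles, reseeds, status = _grow_kernel(
            seed, gp.s, gp.e, p_branch, gp.mass_target, gp.branch_angle_range, gp.max_reseeds
        )
        if status == 1:
            raise NetworkGrowthError(
                f"mass target {gp.mass_target} not reached after {gp.max_reseeds} re-seeds"
            )
        if status == 2:  # pragma: no cover - needs pathological parameters
            raise NetworkGrowthError("tip/segment capacity exceeded")
    else:
        edges, angles, reseeds = _grow_python(gp, rng)
    return NetworkStructure(
        edges, seed_angles=angles, reseed_count=reseeds, resolution=gp.e
    )


def sample_network_point(
    net: NetworkStructure, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Sample points uniformly by arc length over the whole network.

    Returns shape ``(2,)`` if ``size`` is None, else ``(size, 2)``.
    """
    starts, vecs, lens, cum = net.flattened_edges()
    if len(lens) == 0 or cum[-1] <= 0:
        raise ValueError("cannot sample from an empty network")
    n = 1 if size is None else size
    t = rng.uniform(0.0, cum[-1], size=n)
    idx = np.minimum(np.searchsorted(cum, t, side="left"), len(lens) - 1)
    frac = (t - (cum[idx] - lens[idx])) / lens[idx]
    pts = starts[idx] + frac[:, None] * vecs[idx]
    return pts[0] if size is None else pts


def mass_in_sector(net: NetworkStructure, sector_start: float, sector_angle: float) -> float:
    """Arc length of network inside the sector [start, start + angle).

    Computed by subdividing edges to pieces no longer than the network's
    growth resolution and classifying piece midpoints by polar angle; the
    error is O(resolution) per sector-boundary crossing.
    """
    if not 0.0 < sector_angle <= _TWO_PI:
        raise ValueError("sector_angle must lie in (0, 2*pi]")
    if sector_angle == _TWO_PI:
        return net.total_mass
    return net.sector_mass(sector_start, sector_angle)


def make_fixture(name: str, n_sides: int = 360) -> NetworkStructure:
    """Deterministic test networks: 'diameter', 'cross' or 'ring'."""
    if name == "diameter":
        segs = [np.array([[-1.0, 0.0], [1.0, 0.0]])]
    elif name == "cross":
        segs = [
            np.array([[-1.0, 0.0], [1.0, 0.0]]),
            np.array([[0.0, -1.0], [0.0, 1.0]]),
        ]
    elif name == "ring":
        ang = _TWO_PI * np.arange(n_sides + 1) / n_sides
        segs = [np.column_stack([0.5 * np.cos(ang), 0.5 * np.sin(ang)])]
    else:
        raise ValueError(f"unknown fixture {name!r} (expected diameter/cross/ring)")
    return NetworkStructure.from_segments(segs, resolution=0.01)


def write_network(net: NetworkStructure, path: str | Path, params: dict | None = None) -> None:
    """Write a plain-text segment list (one polyline per line, x y pairs).

    A JSON sidecar ``<path>.json`` records generating parameters, if given.
    """
    path = Path(path)
    with path.open("w") as fh:
        for seg in net.segments:
            fh.write(" ".join(f"{v:.12g}" for v in seg.ravel()) + "\n")
    if params is not None:
        sidecar = dict(params)
        sidecar["total_mass"] = net.total_mass
        sidecar["reseed_count"] = net.reseed_count
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_network(path: str | Path, resolution: float = 0.01) -> NetworkStructure:
    segs = []
    for line in Path(path).read_text().splitlines():
        vals = np.fromstring(line, sep=" ")
        if vals.size >= 4:
            segs.append(vals.reshape(-1, 2))
    return NetworkStructure.from_segments(segs, resolution=resolution)
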