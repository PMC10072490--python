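"""Parameter sweeps over network-inclusion grids, with matched theory.

Reproduces the structure of the heat-map experiments: for each cell of a
(p, q) grid (crossed with seed counts, heteroplasmies, copy numbers and
diffusion scales) an independent Monte-Carlo ensemble is run, a beta law is
fitted to the empirical inherited-network-fraction moments, and the matching
analytic predictions (binomial null baseline, closed forms, first-order
Taylor, exhaustive sum where tractable) are attached to the same row of a
long-format table.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analytic import (
    ModelSpec,
    binomial_null,
    closed_form_copy_number,
    closed_form_heteroplasmy,
    exact_moments_sum,
    fit_beta,
    moments_random,
    taylor_first_order,
)
from .division import DivisionParams, run_ensemble
from .network import GrowthParams
from .population import DiffusionParams, GeneticParams, PlacementParams

__all__ = ["SweepSpec", "run_sweep", "compare_sim_vs_theory"]

log = logging.getLogger("mitopart.sweep")


def _default_grid() -> list[float]:
    return [round(0.1 * i, 10) for i in range(11)]


@dataclass
class SweepSpec:
    """Axes and settings of one sweep; the cross product defines the cells."""

    p_grid: list[float] = field(default_factory=_default_grid)
    q_grid: list[float] = field(default_factory=_default_grid)
    seeds_list: list[int] = field(default_factory=lambda: [4, 16, 64])
    h_list: list[float] = field(default_factory=lambda: [0.1, 0.5])
    N0_list: list[int] = field(default_factory=lambda: [100, 1000])
    p_c: float = 0.5
    placement_mode: str = "random"
    l: float = 0.0
    lam_list: list[float] = field(default_factory=lambda: [0.0])
    reps: int = 2000
    master_seed: int = 0
    mass_target: float = 50.0
    exact_max_n0: int = 200

    def __post_init__(self) -> None:
        for name in ("p_grid", "q_grid", "seeds_list", "h_list", "N0_list", "lam_list"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        if self.reps < 2:
            raise ValueError("reps must be >= 2")

    def cells(self):
        return itertools.product(
            self.seeds_list, self.N0_list, self.h_list, self.lam_list, self.p_grid, self.q_grid
        )


def _analytic_columns(
    N0: int, h: float, p: float, q: float, p_c: float, E_U, V_U, lam: float,
    placement_mode: str, l: float, mass_target: float, exact_ok: bool,
) -> dict:
    """Theory columns for one cell, computed with the cell's fitted Beta(a, b)."""
    cols: dict = {}
    null = binomial_null(N0, h, p_c)
    cols["null_V_N"] = null.V_N
    cols["null_Vp_h"] = null.Vp_h
    try:
        bp = fit_beta(E_U, V_U)
    except ValueError:
        log.warning("infeasible beta fit (E_U=%s, V_U=%s); analytic columns null", E_U, V_U)
        cols.update(
            alpha=np.nan, beta=np.nan, cf_V_N=np.nan, cf_Vp_h=np.nan,
            t1_Vp_h=np.nan, exact_V_N=np.nan, exact_Vp_h=np.nan, beta_fit_ok=False,
        )
        return cols
    cols["alpha"], cols["beta"], cols["beta_fit_ok"] = bp.alpha, bp.beta, True
    spec = ModelSpec(N0=N0, h=h, p=p, q=q, p_c=p_c, beta_params=bp, mode="random")
    cols["cf_V_N"] = closed_form_copy_number(spec)
    cols["cf_Vp_h"] = closed_form_heteroplasmy(spec) if 0 < h < 1 else np.nan
    t1 = taylor_first_order(moments_random(spec), h)
    cols["t1_Vp_h"] = t1.Vp_h if t1.Vp_h is not None else np.nan
    # the network-placement theory describes the undiffused, random-placement
    # regime; attach exact sums only where they are the matched model
    if exact_ok and lam == 0.0 and placement_mode == "random":
        ex = exact_moments_sum(spec, quad_nodes=128, check_convergence=False)
        cols["exact_V_N"] = ex.V_N
        cols["exact_Vp_h"] = ex.Vp_h if ex.Vp_h is not None else np.nan
    else:
        cols["exact_V_N"] = np.nan
        cols["exact_Vp_h"] = np.nan
    return cols


def run_sweep(spec: SweepSpec, out: str | Path | None = None) -> pd.DataFrame:
    """Run every grid cell and return (and optionally write) the long table.

    Each cell uses an independent child RNG stream spawned deterministically
    from ``(master_seed, cell_index)``, so cells are reproducible regardless
    of execution order.
    """
    rows = []
    cells = list(spec.cells())
    for idx, (s, N0, h, lam, p, q) in enumerate(cells):
        rng = np.random.default_rng(np.random.SeedSequence([spec.master_seed, idx]))
        summary = run_ensemble(
            growth=GrowthParams(s=s, mass_target=spec.mass_target),
            genetics=GeneticParams(N0=N0, h=h, p=p, q=q),
            placement=PlacementParams(mode=spec.placement_mode, l=spec.l),
            diffusion=DiffusionParams(lam=lam) if lam > 0 else None,
            division=DivisionParams.from_p_c(spec.p_c),
            n_reps=spec.reps,
            rng=rng,
        )
        row = {
            "cell": idx, "s": s, "N0": N0, "h": h, "lam": lam, "p": p, "q": q,
            "p_c": spec.p_c, "placement_mode": spec.placement_mode, "l": spec.l,
            "reps": spec.reps,
        }
        row.update(summary.to_dict())
        row.update(
            _analytic_columns(
                N0, h, p, q, spec.p_c, summary.E_U, summary.V_U, lam,
                spec.placement_mode, spec.l, spec.mass_target,
                exact_ok=N0 <= spec.exact_max_n0,
            )
        )
        rows.append(row)
        if (idx + 1) % 10 == 0 or idx + 1 == len(cells):
            log.info("sweep progress: %d/%d cells", idx + 1, len(cells))
    df = pd.DataFrame(rows)
    if out is not None:
        out = Path(out)
        df.to_csv(out, index=False)
        manifest = {
            "tool": "mitopart",
            "version": __version__,
            "spec": asdict(spec),
            "n_cells": len(cells),
        }
        out.with_suffix(out.suffix + ".manifest.json").write_text(
            json.dumps(manifest, indent=1)
        )
    return df


def compare_sim_vs_theory(result: pd.DataFrame) -> pd.DataFrame:
    """Per-cell z-scores of simulated variances against exact-sum theory.

    Adds ``z_V_N`` and ``z_Vp_h`` (simulation minus exact sum over the
    Monte-Carlo standard error) plus the Taylor-vs-exact discrepancies, and
    returns the augmented table; cells with |z| > 3 indicate sim/theory
    disagreement beyond Monte-Carlo noise.
    """
    required = {"V_N", "se_V_N", "exact_V_N", "Vp_h", "se_Vp_h", "exact_Vp_h", "t1_Vp_h"}
    missing = required - set(result.columns)
    if missing:
        raise ValueError(f"result table lacks columns: {sorted(missing)}")
    df = result.copy()
    df["z_V_N"] = (df["V_N"] - df["exact_V_N"]) / df["se_V_N"]
    df["z_Vp_h"] = (df["Vp_h"] - df["exact_Vp_h"]) / df["se_Vp_h"]
    df["taylor_minus_exact_Vp_h"] = df["t1_Vp_h"] - df["exact_Vp_h"]
    return df
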