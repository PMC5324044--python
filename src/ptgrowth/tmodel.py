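"""Geometric carbon-allocation tree growth ("T") model.

Annual potential GPP per unit ground area is converted to a whole-tree
carbon budget and allocated to stem, foliage and fine roots under the
geometric constraints of the tree's architecture:

* asymptotic height-diameter trajectory H(d) = Hmax (1 - exp(-a d / Hmax));
* crown area A_c(d) = (pi c / 4a) d H(d), so the initial crown:stem-section
  ratio is c;
* paraboloid stem (form factor 1/2): W_stem = (pi/8) rho d^2 H;
* foliage W_f = A_c L / sigma and fine roots W_r = zeta L A_c, with L the
  within-crown leaf area index, sigma the specific leaf area and zeta the
  fine-root mass per unit leaf area;
* canopy absorption by Beer's law, fAPAR = 1 - exp(-k L).

NPP = y (GPP_tree (1 - f_foliage_resp) - r_s W_sapwood - r_r W_root); the
annual diameter increment solves the linearized carbon balance
NPP = dW/dd * Dd + turnover, and the ring width is Dd/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SpeciesParams:
    """Species-specific geometry, allocation and respiration parameters.

    Defaults describe a slow-growing montane juniper-like conifer; `lai`
    and `zeta` are the two allocation parameters the glacial experiments
    re-optimize.
    """

    a: float = 60.0            # initial height-diameter slope (m m-1)
    c_ratio: float = 150.0     # initial crown area : stem cross-section
    h_max: float = 12.0        # asymptotic height (m)
    rho_s: float = 205.0       # wood density (kg C m-3)
    lai: float = 1.8           # leaf area index within the crown, L
    sla: float = 7.0           # specific leaf area sigma (m2 kg-1 C)
    tau_f: float = 4.0         # foliage turnover time (a)
    tau_r: float = 1.25        # fine-root turnover time (a)
    r_s: float = 0.04          # sapwood specific respiration (a-1)
    r_r: float = 0.913         # fine-root specific respiration (a-1)
    zeta: float = 0.6          # fine-root mass per unit leaf area (kg C m-2)
    yield_: float = 0.6        # growth-respiration yield y
    k_ext: float = 0.5         # PAR extinction coefficient
    huber_inv: float = 3000.0  # leaf area per unit sapwood area (m2 m-2)
    foliage_resp_frac: float = 0.10  # fraction of GPP respired by foliage

    def __post_init__(self):
        vals = [self.a, self.c_ratio, self.h_max, self.rho_s, self.lai, self.sla,
                self.tau_f, self.tau_r, self.r_s, self.r_r, self.zeta,
                self.yield_, self.k_ext, self.huber_inv]
        if any(not np.isfinite(v) or v <= 0 for v in vals):
            raise ValueError("species parameters must be positive and finite")
        if self.yield_ > 1 or not 0 <= self.foliage_resp_frac < 1:
            raise ValueError("yield must be <= 1 and foliage_resp_frac in [0, 1)")

    def with_(self, **kwargs) -> "SpeciesParams":
        return replace(self, **kwargs)


@dataclass
class TreeState:
    """Tree dimensions and carbon pools, all derived from diameter."""

    diameter: float
    height: float
    crown_area: float
    w_stem: float
    w_sapwood: float
    w_foliage: float
    w_root: float


@dataclass
class RingSeries:
    """Annual ring widths (mm) indexed by ring year, with provenance metadata."""

    widths: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.widths < 0).any():
            raise ValueError("ring widths must be non-negative")
        self.widths = self.widths.astype(float).rename("rw_mm")

    @property
    def years(self) -> np.ndarray:
        return self.widths.index.to_numpy()

    def mean_width(self) -> float:
        return float(self.widths.mean())


# ----------------------------------------------------------------------
# geometry
# ----------------------------------------------------------------------

def height_from_diameter(d: float, params: SpeciesParams) -> float:
    """Asymptotic height-diameter curve; slope a at d=0, asymptote h_max."""
    if d < 0:
        raise ValueError("diameter must be non-negative")
    return params.h_max * (1.0 - np.exp(-params.a * d / params.h_max))


def crown_area(d: float, h: float, params: SpeciesParams) -> float:
    """Crown projected area; equals c_ratio x stem cross-section for small trees."""
    return (np.pi * params.c_ratio / (4.0 * params.a)) * d * h


def fapar(lai: float, k_ext: float) -> float:
    """Beer's-law fraction of incident PAR absorbed by the canopy."""
    if lai < 0:
        raise ValueError("LAI must be non-negative")
    return 1.0 - np.exp(-k_ext * lai)


def biomass_pools(d: float, params: SpeciesParams) -> TreeState:
    """All pools from diameter: stem (paraboloid), sapwood (pipe model), foliage, roots."""
    h = height_from_diameter(d, params)
    ac = crown_area(d, h, params)
    leaf_area = ac * params.lai
    w_stem = (np.pi / 8.0) * params.rho_s * d * d * h
    w_foliage = leaf_area / params.sla
    w_root = params.zeta * leaf_area
    w_sapwood = params.rho_s * (leaf_area / params.huber_inv) * h / 2.0
    return TreeState(d, h, ac, w_stem, w_sapwood, w_foliage, w_root)


def _marginal_masses(d: float, params: SpeciesParams) -> tuple[float, float, float]:
    """(dW_stem/dd, dW_foliage/dd, dW_root/dd) via the chain rule through H(d), A_c(d)."""
    h = height_from_diameter(d, params)
    dh_dd = params.a * np.exp(-params.a * d / params.h_max)
    ac_coeff = np.pi * params.c_ratio / (4.0 * params.a)
    dac_dd = ac_coeff * (h + d * dh_dd)
    dws = (np.pi / 8.0) * params.rho_s * (2.0 * d * h + d * d * dh_dd)
    dwf = (params.lai / params.sla) * dac_dd
    dwr = params.zeta * params.lai * dac_dd
    return dws, dwf, dwr


# ----------------------------------------------------------------------
# carbon budget
# ----------------------------------------------------------------------

def npp_annual(gpp_potential: float, state: TreeState, params: SpeciesParams) -> float:
    """Whole-tree NPP (kg C a-1) from potential GPP per unit ground area.

    GPP_tree = gpp_potential x fAPAR x crown area; foliage respiration is a
    fixed fraction of GPP, growth respiration is (1 - y) of the remainder,
    sapwood and fine-root maintenance are mass-proportional.  Floored at 0.
    """
    if gpp_potential < 0:
        raise ValueError("potential GPP must be non-negative")
    p_tree = gpp_potential * fapar(params.lai, params.k_ext) * state.crown_area
    npp = params.yield_ * (
        p_tree * (1.0 - params.foliage_resp_frac)
        - params.r_s * state.w_sapwood
        - params.r_r * state.w_root
    )
    return max(0.0, npp)


def _total_mass(d: float, params: SpeciesParams) -> float:
    s = biomass_pools(d, params)
    return s.w_stem + s.w_foliage + s.w_root


def diameter_increment(npp: float, state: TreeState, params: SpeciesParams) -> float:
    """Annual diameter increment (m) from the whole-tree carbon balance.

    NPP first pays foliage and fine-root turnover; what remains drives the
    coupled stem/foliage/root increments.  The analytic marginal-mass
    derivative gives the first-order increment, which a few Newton steps on
    the exact mass difference W(d+Dd) - W(d) then refine, so the balance
    closes to machine precision even for large increments.  When turnover
    exceeds NPP the increment is floored at 0 (no shrinkage).
    """
    if npp < 0:
        raise ValueError("NPP must be non-negative")
    d = state.diameter
    turnover = state.w_foliage / params.tau_f + state.w_root / params.tau_r
    available = npp - turnover
    if available <= 0.0:
        return 0.0
    dws, dwf, dwr = _marginal_masses(d, params)
    dd = available / (dws + dwf + dwr)  # linearized start
    w0 = _total_mass(d, params)
    for _ in range(8):
        resid = _total_mass(d + dd, params) - w0 - available
        slope = sum(_marginal_masses(d + dd, params))
        step = resid / slope
        dd -= step
        if abs(step) <= 1e-14 * max(dd, 1e-12):
            break
    return max(0.0, dd)


def allocation_fractions(npp: float, state: TreeState, dd: float,
                         params: SpeciesParams) -> dict[str, float]:
    """Fractions of NPP to foliage (increment + turnover), roots and stem.

    Undefined at NPP = 0 (returns NaNs).  Fractions sum to 1 exactly when
    the increment is interior (not floored).
    """
    if npp <= 0:
        return {"foliage": float("nan"), "root": float("nan"), "stem": float("nan")}
    after = biomass_pools(state.diameter + dd, params)
    f_fol = (after.w_foliage - state.w_foliage + state.w_foliage / params.tau_f) / npp
    f_root = (after.w_root - state.w_root + state.w_root / params.tau_r) / npp
    f_stem = (after.w_stem - state.w_stem) / npp
    return {"foliage": f_fol, "root": f_root, "stem": f_stem}


# ----------------------------------------------------------------------
# the annual growth loop
# ----------------------------------------------------------------------

def simulate_rings(gpp_annual: pd.Series, params: SpeciesParams,
                   d0: float = 0.3, record_budget: bool = False):
    """Grow a tree through a series of ring years.

    ``gpp_annual`` is potential GPP (kg C m-2 a-1) per ring year, already
    accumulated over the 24-month window.  Returns a :class:`RingSeries`;
    with ``record_budget=True`` also a per-year budget frame used by the
    carbon-conservation diagnostics.
    """
    if d0 <= 0:
        raise ValueError("initial diameter must be positive")
    d = float(d0)
    widths, budget = {}, []
    for year, gpp in gpp_annual.items():
        state = biomass_pools(d, params)
        npp = npp_annual(float(gpp), state, params)
        dd = diameter_increment(npp, state, params)
        widths[int(year)] = dd / 2.0 * 1000.0  # mm of radius
        if record_budget:
            turnover = state.w_foliage / params.tau_f + state.w_root / params.tau_r
            budget.append(
                {
                    "year": int(year),
                    "npp": npp,
                    "increment": _total_mass(d + dd, params) - _total_mass(d, params),
                    "turnover": turnover,
                    "floored": npp <= turnover,
                }
            )
        d += dd
    rings = RingSeries(
        pd.Series(widths, dtype=float).rename_axis("year"),
        meta={"d0": d0, "d_final": d, "params": params},
    )
    if record_budget:
        return rings, pd.DataFrame(budget).set_index("year") if budget else pd.DataFrame()
    return rings


def simulate_growth(forcing, params: SpeciesParams, d0: float = 0.3,
                    constants=None, **pmodel_kwargs) -> RingSeries:
    """Full forward model: prepared forcing -> P-model -> annual rings."""
    from . import pmodel as _pm

    consts = constants or _pm.DEFAULT_CONSTANTS
    monthly = _pm.run_pmodel(forcing, consts, **pmodel_kwargs)
    gpp_annual = _pm.annual_potential_gpp(monthly)
    return simulate_rings(gpp_annual, params, d0=d0)


__all__ = [
    "SpeciesParams",
    "TreeState",
    "RingSeries",
    "height_from_diameter",
    "crown_area",
    "fapar",
    "biomass_pools",
    "npp_annual",
    "diameter_increment",
    "allocation_fractions",
    "simulate_rings",
    "simulate_growth",
]
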