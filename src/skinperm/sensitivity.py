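"""Morris elementary-effects screening of permeability-model parameters.

One-at-a-time randomized trajectories over the literature uncertainty ranges
of the uncertain model inputs; per parameter the screen reports mu* (mean
absolute elementary effect — overall influence on the output) and sigma
(standard deviation of the elementary effects — interaction/nonlinearity).
The output of interest is log10 of the aggregate permeability, so effects are
in decades per full parameter range.

Log-scaled quantities (permeabilities, partition/diffusion coefficients,
pore geometry, the lumped follicle density) are sampled in log space; the
orifice/shaft radius ratio is sampled linearly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from skinperm import core
from skinperm.core import EffectiveParams, Registry, default_registry

__all__ = [
    "ParamRange",
    "MorrisResult",
    "morris_screen",
    "permeability_screen_setup",
    "screen_scenario",
    "select_inference_parameters",
    "SCREEN_SCENARIOS",
]

#: compound x vehicle-pH scenarios screened in the design study
SCREEN_SCENARIOS = (
    ("fentanyl", 7.40),
    ("fentanyl", 9.37),
    ("sufentanil", 7.40),
    ("sufentanil", 9.37),
)


@dataclass(frozen=True)
class ParamRange:
    """Screening range for one factor; ``scale`` is 'linear' or 'log'."""

    lo: float
    hi: float
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.lo > self.hi:
            raise ValueError("range must satisfy lo <= hi")
        if self.scale == "log" and self.lo <= 0:
            raise ValueError("log-scaled range requires positive bounds")

    def from_unit(self, u):
        """Map u in [0, 1] to the parameter value."""
        if self.scale == "log":
            return self.lo * (self.hi / self.lo) ** u
        return self.lo + (self.hi - self.lo) * u


@dataclass(frozen=True)
class MorrisResult:
    parameter: str
    mu_star: float
    sigma: float
    scenario: str = ""

    def __post_init__(self) -> None:
        if self.mu_star < 0 or self.sigma < 0:
            raise ValueError("mu_star and sigma must be >= 0")


def morris_screen(
    output_fn: Callable[[Mapping[str, float]], float],
    param_ranges: Mapping[str, ParamRange],
    n_trajectories: int = 100,
    n_levels: int = 4,
    seed: int = 0,
    scenario: str = "",
) -> list[MorrisResult]:
    """Randomized one-at-a-time elementary-effects screen.

    Effects are computed on the unit hypercube (step delta = p/(2(p-1))), so
    mu*/sigma are in output units per full parameter range.  Degenerate
    ranges (lo == hi) are reported with mu* = sigma = 0 and a warning.
    """
    if n_trajectories < 2:
        raise ValueError("need at least 2 trajectories")
    if n_levels < 2 or n_levels % 2:
        raise ValueError("n_levels must be an even integer >= 2")
    names = list(param_ranges)
    active = [n for n in names if param_ranges[n].lo < param_ranges[n].hi]
    for n in names:
        if n not in active:
            warnings.warn(f"degenerate range for {n!r}: reported with mu*=0")
    k = len(active)
    p = n_levels
    delta = p / (2.0 * (p - 1.0))
    grid = np.arange(p // 2) / (p - 1.0)  # start levels that allow +delta
    rng = np.random.default_rng(seed)

    effects: dict[str, list[float]] = {n: [] for n in active}
    for _ in range(n_trajectories):
        u = grid[rng.integers(0, grid.size, size=k)].astype(float)
        direction = np.where(rng.random(k) < 0.5, 1.0, -1.0)
        # flip a +delta start into a -delta start where possible
        u = np.where(direction < 0, u + delta, u)
        y = output_fn(_values(active, u, param_ranges, names, param_ranges))
        order = rng.permutation(k)
        for j in order:
            u2 = u.copy()
            u2[j] = u[j] + direction[j] * delta
            y2 = output_fn(_values(active, u2, param_ranges, names, param_ranges))
            effects[active[j]].append((y2 - y) / (direction[j] * delta))
            u, y = u2, y2

    out = []
    for n in names:
        if n in active:
            ee = np.asarray(effects[n])
            out.append(
                MorrisResult(n, float(np.abs(ee).mean()), float(ee.std(ddof=1)), scenario)
            )
        else:
            out.append(MorrisResult(n, 0.0, 0.0, scenario))
    return out


def _values(active, u, ranges, all_names, param_ranges) -> dict[str, float]:
    vals = {n: param_ranges[n].from_unit(0.5) for n in all_names}  # degenerate: mid
    for n, ui in zip(active, u):
        vals[n] = ranges[n].from_unit(float(ui))
    return vals


# ---------------------------------------------------------------------------
# Permeability-model screening scenarios
# ---------------------------------------------------------------------------


def default_screen_ranges(
    compound: str,
    vehicle_pH: float,
    site: str = "thigh",
    registry: Registry | None = None,
) -> dict[str, ParamRange]:
    """Literature uncertainty ranges of the uncertain model inputs.

    Trans-bilayer permeability, partition and diffusion coefficients take
    their QSPR nominal +/- the published log10 uncertainty; skin geometry
    takes its published min-max range.  Follicle density and the open
    fraction enter the model as a product and are screened as one lumped
    factor.
    """
    reg = registry if registry is not None else default_registry()
    c = reg.compound(compound)
    fixed = reg.fixed_params("heat-separated")
    ktrans_nom = core.nominal_log10_ktrans(c.MW)
    klipw_nom = core.nominal_log10_Klipw(c.logKow)
    kinfw_nom = core.nominal_log10_Kinfw(c.pKa, vehicle_pH)
    dinf_nom = core.nominal_log10_Dinf(c.MW, fixed.ADaq, fixed.BDaq)
    nf_nom = reg.site(site).Nf_nom
    hsc_range = {"thigh": (13.0, 65.0), "abdomen": (19.0, 97.0)}[site]
    return {
        "log10_ktrans": ParamRange(ktrans_nom - 1.08, ktrans_nom + 1.08),
        "log10_Klipw": ParamRange(klipw_nom - 0.434, klipw_nom + 0.434),
        "log10_Kinfw": ParamRange(kinfw_nom - 1.0, kinfw_nom + 1.0),
        "log10_Dinf": ParamRange(dinf_nom - 1.0, dinf_nom + 1.0),
        "hSC_um": ParamRange(*hsc_range, scale="log"),
        "my_um": ParamRange(2.32, 3.63, scale="log"),
        "Nf_fopen": ParamRange(12.0 * fixed.fopen_nom, 36.0 * fixed.fopen_nom, scale="log"),
        "r1_over_r0": ParamRange(1.0, 10.0),
        "r2_nm": ParamRange(0.16, 16.0, scale="log"),
        "Np_per_cm2": ParamRange(3.73e4, 3.73e6, scale="log"),
    }


def permeability_screen_setup(
    compound: str,
    vehicle_pH: float,
    site: str = "thigh",
    preparation: str = "heat-separated",
    registry: Registry | None = None,
):
    """Build (output_fn, ranges) for screening log10 P_tot/w in one scenario."""
    reg = registry if registry is not None else default_registry()
    c = reg.compound(compound)
    fixed = reg.fixed_params(preparation)
    fnon = core.fraction_nonionized(c.pKa, vehicle_pH)
    dinf_nom = core.nominal_log10_Dinf(c.MW, fixed.ADaq, fixed.BDaq)
    r_sol = core.solute_radius_cm(c.MW, fixed.solute_density)
    ranges = default_screen_ranges(compound, vehicle_pH, site, reg)

    def output_fn(x: Mapping[str, float]) -> float:
        hSC = x["hSC_um"] * 1e-4
        my = x["my_um"] * 1e-4
        eff = EffectiveParams(
            hSC=hSC,
            my=my,
            ktrans=10.0 ** x["log10_ktrans"],
            Klipw=10.0 ** x["log10_Klipw"],
            Kinfw=10.0 ** x["log10_Kinfw"],
            Dinf=10.0 ** x["log10_Dinf"],
            Daq=10.0 ** dinf_nom,
            fopen=1.0,  # lumped into Nf
            Nf=x["Nf_fopen"],
            r0=fixed.r0 * 1e-4,
            r1=fixed.r0 * x["r1_over_r0"] * 1e-4,
            r2=x["r2_nm"] * 1e-7,
            Np=x["Np_per_cm2"],
            hed=fixed.hed * 1e-4,
            hde=fixed.hde * 1e-4,
            K_viable_w=fixed.K_viable_w,
            viable_tortuosity=fixed.viable_tortuosity,
            r_solute=r_sol,
            n_bilayers=fixed.bilayers_per_cc_layer * hSC / my,
        )
        return math.log10(core.pathway_permeabilities(eff, fnon).P_tot_w)

    return output_fn, ranges


def screen_scenario(
    compound: str,
    vehicle_pH: float,
    n_trajectories: int = 100,
    n_levels: int = 4,
    seed: int = 0,
    site: str = "thigh",
    registry: Registry | None = None,
) -> list[MorrisResult]:
    """Morris screen of log10 P_tot/w for one compound x pH scenario."""
    fn, ranges = permeability_screen_setup(compound, vehicle_pH, site, registry=registry)
    label = f"{compound}@pH{vehicle_pH:g}"
    return morris_screen(fn, ranges, n_trajectories, n_levels, seed, scenario=label)


#: screening factor -> inferred parameter(s) in the calibration
_FACTOR_TO_INFERRED = {
    "hSC_um": ("hSC",),
    "log10_ktrans": ("ktrans",),
    "log10_Klipw": ("Klip/w",),
    "log10_Kinfw": ("Kinf/w",),
    "log10_Dinf": ("Dinf",),
    "Nf_fopen": ("Nf", "fopen"),
    "r1_over_r0": ("Nf",),  # orifice geometry lumped into the Nf scaling
    "my_um": ("my",),
    "r2_nm": ("r2",),
    "Np_per_cm2": ("Np",),
}


def select_inference_parameters(
    results: Sequence[MorrisResult],
    threshold_policy: float | Callable[[np.ndarray], np.ndarray] = 0.1,
) -> dict[str, list[str]]:
    """Partition parameters into retained/excluded from screening results.

    ``results`` must cover all four compound x pH scenarios.  With the
    default policy a factor is excluded when its mu* stays below
    ``threshold_policy`` times the scenario maximum in every scenario
    (0 admits everything).  Returns ``{"retained": [...], "excluded": [...]}``
    in inferred-parameter naming.
    """
    scen = {}
    for r in results:
        scen.setdefault(r.scenario, []).append(r)
    expected = {f"{c}@pH{ph:g}" for c, ph in SCREEN_SCENARIOS}
    if set(scen) != expected:
        missing = sorted(expected - set(scen))
        raise ValueError(f"missing scenario results: {missing}")

    influential: set[str] = set()
    all_factors: set[str] = set()
    for label, rs in scen.items():
        mu = np.array([r.mu_star for r in rs])
        cut = threshold_policy * mu.max() if np.isscalar(threshold_policy) else threshold_policy(mu)
        for r, m in zip(rs, mu):
            all_factors.add(r.parameter)
            if m >= cut:
                influential.add(r.parameter)

    retained: list[str] = []
    excluded: list[str] = []
    for factor in sorted(all_factors):
        targets = _FACTOR_TO_INFERRED.get(factor, (factor,))
        for t in targets:
            bucket = retained if factor in influential else excluded
            if t not in retained and t not in excluded:
                bucket.append(t)
    # a parameter influential through any factor stays retained
    for factor in sorted(influential):
        for t in _FACTOR_TO_INFERRED.get(factor, (factor,)):
            if t in excluded:
                excluded.remove(t)
                retained.append(t)
    return {"retained": sorted(retained), "excluded": sorted(excluded)}
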