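"""Steady-state mechanistic skin permeability model.

The aggregate permeability coefficient ``P_tot/w`` (cm/s, referenced to the
total solute concentration in an aqueous vehicle) is composed as a
series/parallel conductance network of three transport routes:

* a non-polar transcellular route across the stratum corneum (SC) lipid
  lamellae, carrying only the non-ionized solute fraction;
* a polar route through water-filled micropores in the SC lipid matrix;
* an appendageal (follicular/infundibular) shunt that bypasses the SC.

The SC routes (lipid + micropore, in parallel) act in series with the viable
epidermis/dermis; the follicular shunt is in parallel with that series
combination.  Every uncertain quantity enters as a scaling or additive
log10 perturbation of a nominal value (:class:`ScalingSet`), so the identity
scaling reproduces the average-individual prediction exactly.

All numeric functions are written as numpy-broadcastable expressions: scalars
in, scalars out; arrays in, arrays out.  Lengths are converted to cm at one
boundary (:func:`apply_scalings`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

AVOGADRO = 6.02214076e23  # 1/mol

__all__ = [
    "Compound",
    "CompoundNominals",
    "SiteNominals",
    "FixedSkinParams",
    "ScalingSet",
    "ExperimentContext",
    "EffectiveParams",
    "PathwayPermeabilities",
    "Registry",
    "default_registry",
    "fraction_nonionized",
    "nominal_log10_ktrans",
    "nominal_log10_Klipw",
    "nominal_log10_Kinfw",
    "nominal_log10_Dinf",
    "compound_nominals",
    "apply_scalings",
    "follicular_permeability",
    "micropore_permeability",
    "sc_lipid_pathway_permeability",
    "viable_tissue_permeability",
    "total_permeability",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Compound:
    """Permeant descriptors: molecular weight, basic pKa, lipophilicity."""

    name: str
    MW: float
    pKa: float
    logKow: float

    def __post_init__(self) -> None:
        if not (self.MW > 0):
            raise ValueError(f"MW must be > 0, got {self.MW}")
        if not (0.0 <= self.pKa <= 14.0):
            raise ValueError(f"pKa must lie in [0, 14], got {self.pKa}")
        if not math.isfinite(self.logKow):
            raise ValueError("logKow must be finite")


@dataclass(frozen=True)
class CompoundNominals:
    """Nominal (QSPR-derived) compound-specific model inputs.

    log10_ktrans : trans-bilayer permeability, log10 cm/s
    log10_Klipw  : SC-lipid/water partition coefficient, log10
    log10_Kinfw  : infundibulum/water partition coefficient, log10
    log10_Dinf   : infundibular diffusivity, log10 cm^2/s
    fnon         : non-ionized fraction in the vehicle, (0, 1]
    """

    log10_ktrans: float
    log10_Klipw: float
    log10_Kinfw: float
    log10_Dinf: float
    fnon: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{f.name} must be finite")
        if not (0.0 < self.fnon <= 1.0):
            raise ValueError(f"fnon must lie in (0, 1], got {self.fnon}")


@dataclass(frozen=True)
class SiteNominals:
    """Anatomical-site nominal skin geometry (lengths in um)."""

    name: str
    hSC_nom: float  # um, fully hydrated SC thickness
    Nf_nom: float  # follicles / cm^2
    r1_over_r0: float  # orifice radius / hair shaft radius

    def __post_init__(self) -> None:
        if not (self.hSC_nom > 0):
            raise ValueError("hSC_nom must be > 0")
        if not (self.Nf_nom > 0):
            raise ValueError("Nf_nom must be > 0")
        if not (self.r1_over_r0 >= 1.0):
            raise ValueError("r1_over_r0 must be >= 1")


@dataclass(frozen=True)
class FixedSkinParams:
    """Quantities held at nominal in all inference paths (lengths in um/nm)."""

    hed: float  # viable epidermis thickness, um
    hde: float  # dermis thickness, um (0 for heat-separated epidermis)
    my: float  # bilayer envelope + corneocyte thickness, um
    fopen_nom: float  # proportion of open follicles
    r0: float  # hair shaft radius, um
    r2: float  # micropore radius, nm
    Np: float  # micropores / cm^2
    ADaq: float  # aqueous diffusivity correlation intercept
    BDaq: float  # aqueous diffusivity correlation slope (on log10 MW)
    bilayers_per_cc_layer: float
    K_viable_w: float
    viable_tortuosity: float
    solute_density: float  # g/cm^3

    def __post_init__(self) -> None:
        if self.hde not in (0.0, 100.0):
            raise ValueError(
                "hde must be 0 (heat-separated) or 100 um (dermatomed), "
                f"got {self.hde}"
            )
        if not (0.0 < self.fopen_nom <= 1.0):
            raise ValueError("fopen_nom must lie in (0, 1]")
        if self.Np < 0:
            raise ValueError("Np must be >= 0")
        if not (self.r2 > 0):
            raise ValueError("r2 must be > 0")


@dataclass(frozen=True)
class ScalingSet:
    """Scalings/perturbations applied to nominal parameters.

    Multiplicative entries default to 1, additive log10 perturbations to 0;
    the default instance is the identity element and reproduces nominal
    predictions exactly.
    """

    hSC_site: float = 1.0
    hSC_ind: float = 1.0
    dlog10_ktrans_cmp: float = 0.0
    dlog10_ktrans_ind: float = 0.0
    dlog10_Klipw_cmp: float = 0.0
    dlog10_Kinfw_cmp: float = 0.0
    dlog10_Dinf_ind: float = 0.0
    dlog10_fopen_ind: float = 0.0
    Nf_site: float = 1.0

    MULTIPLICATIVE = ("hSC_site", "hSC_ind", "Nf_site")

    def compose(self, other: "ScalingSet") -> "ScalingSet":
        """Component-wise composition: multiplicative entries multiply,
        additive perturbations add."""
        out = {}
        for f in fields(self):
            a, b = getattr(self, f.name), getattr(other, f.name)
            out[f.name] = a * b if f.name in self.MULTIPLICATIVE else a + b
        return ScalingSet(**out)


@dataclass(frozen=True)
class ExperimentContext:
    """A single measurement context: compound, site, preparation, vehicle."""

    compound: str
    site: str
    preparation: str  # "heat-separated" | "dermatomed"
    vehicle_pH: float
    individual_id: str = "average"

    def __post_init__(self) -> None:
        if not (0.0 <= self.vehicle_pH <= 14.0):
            raise ValueError(f"vehicle_pH must lie in [0, 14], got {self.vehicle_pH}")
        if self.preparation not in ("heat-separated", "dermatomed"):
            raise ValueError(f"unknown preparation {self.preparation!r}")


@dataclass(frozen=True)
class EffectiveParams:
    """Scaled model inputs, all lengths in cm (the unit boundary)."""

    hSC: float  # cm
    my: float  # cm
    ktrans: float  # cm/s
    Klipw: float
    Kinfw: float
    Dinf: float  # cm^2/s
    Daq: float  # cm^2/s (aqueous diffusivity of the permeant)
    fopen: float
    Nf: float  # 1/cm^2
    r0: float  # cm
    r1: float  # cm
    r2: float  # cm
    Np: float  # 1/cm^2
    hed: float  # cm
    hde: float  # cm
    K_viable_w: float
    viable_tortuosity: float
    r_solute: float  # cm
    n_bilayers: float  # transport-limiting bilayer count


@dataclass(frozen=True)
class PathwayPermeabilities:
    """Pathway-resolved output of the steady-state model (all cm/s)."""

    P_tot_w: float
    k_trans_w: float  # ktrans * Klip/w, trans-bilayer permeability rel. water
    P_sc_lipid: float  # SC lipid pathway branch permeability
    P_inf_w: float  # infundibular shunt branch permeability
    P_pore: float  # micropore branch permeability
    P_viable: float  # viable epidermis + dermis series permeability


# ---------------------------------------------------------------------------
# Registry (packaged nominal values)
# ---------------------------------------------------------------------------


class Registry:
    """Compound/site/constant registry backed by the packaged YAML file."""

    def __init__(self, config: Mapping) -> None:
        self._cfg = _validate_config(config)
        self.compounds = {
            name: Compound(name=name, **vals)
            for name, vals in self._cfg["compounds"].items()
        }
        self.sites = {
            name: SiteNominals(
                name=name,
                hSC_nom=vals["hSC_nom_um"],
                Nf_nom=vals["Nf_nom_per_cm2"],
                r1_over_r0=vals["r1_over_r0"],
            )
            for name, vals in self._cfg["sites"].items()
        }
        self.qspr = self._cfg["qspr"]

    @classmethod
    def from_packaged(cls) -> "Registry":
        text = (
            resources.files("skinperm.data").joinpath("nominals.yaml").read_text()
        )
        return cls(yaml.safe_load(text))

    def compound(self, name: str) -> Compound:
        try:
            return self.compounds[name]
        except KeyError:
            raise KeyError(
                f"unknown compound {name!r}; registered: {sorted(self.compounds)}"
            ) from None

    def site(self, name: str) -> SiteNominals:
        try:
            return self.sites[name]
        except KeyError:
            raise KeyError(
                f"unknown site {name!r}; registered: {sorted(self.sites)}"
            ) from None

    def fixed_params(self, preparation: str) -> FixedSkinParams:
        fx = self._cfg["fixed"]
        try:
            hde = fx["hde_um"][preparation]
        except KeyError:
            raise KeyError(
                f"unknown preparation {preparation!r}; "
                f"supported: {sorted(fx['hde_um'])}"
            ) from None
        return FixedSkinParams(
            hed=fx["hed_um"],
            hde=hde,
            my=fx["my_um"],
            fopen_nom=fx["fopen_nom"],
            r0=fx["r0_um"],
            r2=fx["r2_nm"],
            Np=fx["Np_per_cm2"],
            ADaq=fx["ADaq"],
            BDaq=fx["BDaq"],
            bilayers_per_cc_layer=fx["bilayers_per_cc_layer"],
            K_viable_w=fx["K_viable_w"],
            viable_tortuosity=fx["viable_tortuosity"],
            solute_density=fx["solute_density_g_cm3"],
        )


def _validate_config(cfg: Mapping) -> Mapping:
    for key in ("compounds", "sites", "fixed", "qspr"):
        if key not in cfg:
            raise ValueError(f"constants config missing section {key!r}")
    for name, c in cfg["compounds"].items():
        missing = {"MW", "pKa", "logKow"} - set(c)
        if missing:
            raise ValueError(f"compound {name!r} missing fields {sorted(missing)}")
    for name, s in cfg["sites"].items():
        missing = {"hSC_nom_um", "Nf_nom_per_cm2", "r1_over_r0"} - set(s)
        if missing:
            raise ValueError(f"site {name!r} missing fields {sorted(missing)}")
    return cfg


_DEFAULT_REGISTRY: Registry | None = None


def default_registry() -> Registry:
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = Registry.from_packaged()
    return _DEFAULT_REGISTRY


# ---------------------------------------------------------------------------
# QSPR nominal values
# ---------------------------------------------------------------------------


def fraction_nonionized(pKa, vehicle_pH):
    """Henderson-Hasselbalch non-ionized fraction of a monoprotic base."""
    pKa = np.asarray(pKa, dtype=float)
    pH = np.asarray(vehicle_pH, dtype=float)
    if not (np.all(np.isfinite(pKa)) and np.all(np.isfinite(pH))):
        raise ValueError("pKa and vehicle_pH must be finite")
    out = 1.0 / (1.0 + 10.0 ** (pKa - pH))
    return out if out.ndim else float(out)


def nominal_log10_ktrans(MW, intercept: float = -0.725, slope: float = -0.792):
    """Nominal trans-bilayer permeability, log10 cm/s: a + b * MW^(1/3)."""
    MW = np.asarray(MW, dtype=float)
    if np.any(MW <= 0):
        raise ValueError("MW must be > 0")
    out = intercept + slope * MW ** (1.0 / 3.0)
    return out if out.ndim else float(out)


def nominal_log10_Klipw(logKow, slope: float = 0.81, intercept_factor: float = 0.43):
    """Nominal SC-lipid/water partition coefficient, log10."""
    logKow = np.asarray(logKow, dtype=float)
    if not np.all(np.isfinite(logKow)):
        raise ValueError("logKow must be finite")
    out = slope * logKow + math.log10(intercept_factor)
    return out if out.ndim else float(out)


def nominal_log10_Kinfw(pKa, vehicle_pH):
    """Nominal infundibulum/water partition coefficient, log10(1/fnon)."""
    fnon = fraction_nonionized(pKa, vehicle_pH)
    out = -np.log10(fnon)
    return out if np.ndim(out) else float(out)


def nominal_log10_Dinf(MW, ADaq: float, BDaq: float):
    """Nominal infundibular (aqueous) diffusivity, log10 cm^2/s."""
    MW = np.asarray(MW, dtype=float)
    if np.any(MW <= 0):
        raise ValueError("MW must be > 0")
    if not (math.isfinite(ADaq) and math.isfinite(BDaq)):
        raise ValueError("aqueous diffusivity constants are not configured")
    out = ADaq + BDaq * np.log10(MW)
    return out if out.ndim else float(out)


def compound_nominals(
    compound: Compound, vehicle_pH: float, fixed: FixedSkinParams,
    qspr: Mapping | None = None,
) -> CompoundNominals:
    """Assemble the QSPR nominal inputs for one compound in one vehicle."""
    if qspr is None:
        qspr = default_registry().qspr
    return CompoundNominals(
        log10_ktrans=nominal_log10_ktrans(
            compound.MW, qspr["ktrans"]["intercept"], qspr["ktrans"]["slope"]
        ),
        log10_Klipw=nominal_log10_Klipw(
            compound.logKow, qspr["klipw"]["slope"], qspr["klipw"]["intercept_factor"]
        ),
        log10_Kinfw=nominal_log10_Kinfw(compound.pKa, vehicle_pH),
        log10_Dinf=nominal_log10_Dinf(compound.MW, fixed.ADaq, fixed.BDaq),
        fnon=fraction_nonionized(compound.pKa, vehicle_pH),
    )


def solute_radius_cm(MW, density_g_cm3: float = 1.0):
    """Hydrodynamic solute radius of a unit-density sphere, cm."""
    MW = np.asarray(MW, dtype=float)
    out = (3.0 * MW / (4.0 * math.pi * density_g_cm3 * AVOGADRO)) ** (1.0 / 3.0)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# Scaling application (the unit boundary: um/nm -> cm)
# ---------------------------------------------------------------------------

_UM = 1e-4  # cm per um
_NM = 1e-7  # cm per nm

#: Prior/perturbation support used when `check_support=True`.
SCALING_SUPPORT = {
    "hSC_site": (1.0 / 1.5, 1.5),
    "hSC_ind": (1.0 / 1.5, 1.5),
    "dlog10_ktrans_cmp": (-0.54, 0.54),
    "dlog10_ktrans_ind": (-0.54, 0.54),
    "dlog10_Klipw_cmp": (-0.43, 0.43),
    "dlog10_Kinfw_cmp": (-1.0, 1.0),
    "dlog10_Dinf_ind": (-1.0, 1.0),
    "dlog10_fopen_ind": (-1.0, 1.0),
    "Nf_site": (1.0 / 1.25, 1.25),
}


def check_scaling_support(scalings: ScalingSet) -> None:
    """Raise ValueError if any scaling lies outside its prior support."""
    for name, (lo, hi) in SCALING_SUPPORT.items():
        v = getattr(scalings, name)
        if np.any(np.asarray(v) < lo) or np.any(np.asarray(v) > hi):
            raise ValueError(
                f"scaling {name}={v} outside prior support [{lo}, {hi}]"
            )


def apply_scalings(
    site: SiteNominals,
    comp: CompoundNominals,
    fixed: FixedSkinParams,
    scalings: ScalingSet = ScalingSet(),
    MW: float | None = None,
    check_support: bool = True,
) -> EffectiveParams:
    """Combine nominal values with scalings into effective model inputs.

    hSC and Nf scale multiplicatively; ktrans, Klip/w, Kinf/w, Dinf and fopen
    receive additive log10 perturbations; my, r2 and Np stay at nominal.
    """
    if check_support:
        check_scaling_support(scalings)
    hSC = site.hSC_nom * scalings.hSC_site * scalings.hSC_ind * _UM
    my = fixed.my * _UM
    fopen = fixed.fopen_nom * 10.0 ** scalings.dlog10_fopen_ind
    Daq = 10.0 ** comp.log10_Dinf  # nominal Dinf == aqueous diffusivity
    if MW is None:
        # Invert the diffusivity correlation so the solute radius is
        # consistent with the compound even when only nominals are passed.
        MW = 10.0 ** ((comp.log10_Dinf - fixed.ADaq) / fixed.BDaq)
    return EffectiveParams(
        hSC=hSC,
        my=my,
        ktrans=10.0
        ** (comp.log10_ktrans + scalings.dlog10_ktrans_cmp + scalings.dlog10_ktrans_ind),
        Klipw=10.0 ** (comp.log10_Klipw + scalings.dlog10_Klipw_cmp),
        Kinfw=10.0 ** (comp.log10_Kinfw + scalings.dlog10_Kinfw_cmp),
        Dinf=10.0 ** (comp.log10_Dinf + scalings.dlog10_Dinf_ind),
        Daq=Daq,
        fopen=fopen,
        Nf=site.Nf_nom * scalings.Nf_site,
        r0=fixed.r0 * _UM,
        r1=fixed.r0 * site.r1_over_r0 * _UM,
        r2=fixed.r2 * _NM,
        Np=fixed.Np,
        hed=fixed.hed * _UM,
        hde=fixed.hde * _UM,
        K_viable_w=fixed.K_viable_w,
        viable_tortuosity=fixed.viable_tortuosity,
        r_solute=solute_radius_cm(MW, fixed.solute_density),
        n_bilayers=fixed.bilayers_per_cc_layer * hSC / my,
    )


# ---------------------------------------------------------------------------
# Pathway permeabilities (cm/s, referenced to total vehicle concentration)
# ---------------------------------------------------------------------------


def follicular_permeability(eff: EffectiveParams, fnon) -> float:
    """Infundibular shunt permeability.

    The infundibulum is a vehicle-filled truncated cone (radii r0 at the hair
    shaft, r1 at the orifice) spanning the stratum corneum; the frustum
    diffusion conductance per follicle is pi*r0*r1*Dinf/hSC.  Multiplied by
    the open-follicle surface density Nf*fopen and by fnon*Kinf/w (the
    vehicle-to-infundibulum partition referenced to total concentration; at
    the nominal Kinf/w = 1/fnon this product is 1, making the nominal shunt
    pH-independent).
    """
    if np.any(np.asarray(eff.Nf) < 0) or np.any(np.asarray(eff.fopen) < 0):
        raise ValueError("Nf and fopen must be >= 0")
    if np.any(np.asarray(eff.r0) < 0) or np.any(np.asarray(eff.r1) < 0):
        raise ValueError("follicle geometry must be >= 0")
    area_factor = eff.Nf * eff.fopen * math.pi * eff.r0 * eff.r1
    out = area_factor * fnon * eff.Kinfw * eff.Dinf / eff.hSC
    return out if np.ndim(out) else float(out)


def _renkin_hindrance(lam):
    """Renkin hindered-diffusion factor for a sphere in a cylindrical pore."""
    lam = np.asarray(lam, dtype=float)
    h = (1.0 - lam) ** 2 * (
        1.0 - 2.104 * lam + 2.09 * lam**3 - 0.95 * lam**5
    )
    out = np.where(lam < 1.0, np.clip(h, 0.0, None), 0.0)
    return out if out.ndim else float(out)


def micropore_permeability(eff: EffectiveParams) -> float:
    """Polar micropore pathway: hindered aqueous diffusion through Np pores
    of radius r2 across the SC; carries the total (ionized + non-ionized)
    species."""
    lam = eff.r_solute / eff.r2
    out = (
        eff.Np * math.pi * eff.r2**2 * _renkin_hindrance(lam) * eff.Daq / eff.hSC
    )
    return out if np.ndim(out) else float(out)


def sc_lipid_pathway_permeability(eff: EffectiveParams, fnon) -> float:
    """Non-polar transcellular route: fnon * ktrans * Klip/w divided by the
    number of transport-limiting bilayers in the brick-and-mortar geometry."""
    if np.any(np.asarray(eff.hSC) < np.asarray(eff.my)):
        raise ValueError(
            "hSC < my: degenerate layer count (less than one corneocyte layer)"
        )
    out = fnon * eff.ktrans * eff.Klipw / eff.n_bilayers
    return out if np.ndim(out) else float(out)


def viable_tissue_permeability(eff: EffectiveParams) -> float:
    """Series permeability of viable epidermis and dermis (aqueous-like gel).

    Both layers share tissue/water partition K_viable_w and diffusivity
    Daq/tortuosity; zero total thickness means no viable-tissue resistance
    (infinite permeability)."""
    thickness = eff.hed + eff.hde
    D_t = eff.Daq / eff.viable_tortuosity
    with np.errstate(divide="ignore"):
        out = np.where(
            np.asarray(thickness) > 0,
            eff.K_viable_w * D_t / np.where(np.asarray(thickness) > 0, thickness, 1.0),
            np.inf,
        )
    return out if np.ndim(out) else float(out)


def pathway_permeabilities(eff: EffectiveParams, fnon) -> PathwayPermeabilities:
    """Compose the conductance network from effective parameters."""
    p_lip = sc_lipid_pathway_permeability(eff, fnon)
    p_pore = micropore_permeability(eff)
    p_inf = follicular_permeability(eff, fnon)
    p_viable = viable_tissue_permeability(eff)
    p_sc = p_lip + p_pore
    with np.errstate(divide="ignore", invalid="ignore"):
        series = np.where(
            np.asarray(p_sc) > 0,
            1.0 / (1.0 / np.where(np.asarray(p_sc) > 0, p_sc, 1.0) + 1.0 / p_viable),
            0.0,
        )
    p_tot = p_inf + series
    squeeze = float if np.ndim(p_tot) == 0 else np.asarray
    return PathwayPermeabilities(
        P_tot_w=squeeze(p_tot),
        k_trans_w=squeeze(eff.ktrans * eff.Klipw),
        P_sc_lipid=squeeze(p_lip),
        P_inf_w=squeeze(p_inf),
        P_pore=squeeze(p_pore),
        P_viable=squeeze(p_viable),
    )


def total_permeability(
    context: ExperimentContext,
    scalings: ScalingSet = ScalingSet(),
    registry: Registry | None = None,
    check_support: bool = True,
) -> PathwayPermeabilities:
    """Steady-state aggregate permeability and its pathway components.

    With the identity :class:`ScalingSet` this is the average-individual
    prediction for the given compound, site, skin preparation and vehicle pH.
    """
    reg = registry if registry is not None else default_registry()
    compound = reg.compound(context.compound)
    site = reg.site(context.site)
    fixed = reg.fixed_params(context.preparation)
    comp = compound_nominals(compound, context.vehicle_pH, fixed, reg.qspr)
    eff = apply_scalings(
        site, comp, fixed, scalings, MW=compound.MW, check_support=check_support
    )
    return pathway_permeabilities(eff, comp.fnon)
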