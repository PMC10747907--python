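"""Bayesian inference of permeability-model scaling parameters.

The joint posterior over compound-, site- and individual-specific scalings
plus a shared relative measurement-error variance nu^2 is

    p(theta, nu | d)  propto  L(theta, nu | d) * p(theta) * p(nu^2),

with a log-normal likelihood per measurement (natural-log residuals between
the model permeability f and the measured permeability d, shared variance
nu^2), flat/log-uniform priors on the scalings, and p(nu^2) propto 1/nu^2
truncated to a finite interval.

Internally every parameter is sampled in a coordinate where its prior is a
bounded uniform: log10 coordinates for multiplicative scalings (hSC, Nf),
natural coordinates for additive log10 perturbations, and ln(nu^2) for the
error variance.  The sampler is the adaptive block Metropolis-Hastings kernel
in :mod:`skinperm.mcmc`, with one block per parameter class.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from skinperm import core
from skinperm.core import (
    EffectiveParams,
    ExperimentContext,
    Registry,
    ScalingSet,
    default_registry,
)
from skinperm.datasets import ExperimentRecord, TrainingDataSet
from skinperm.mcmc import Block, ChainResult, MCMCConfig, ess_bulk, run_block_mh, split_rhat

__all__ = [
    "PriorSpec",
    "default_priors",
    "ParameterLayout",
    "ParameterVector",
    "PosteriorDraws",
    "DatasetModel",
    "log_prior",
    "log_likelihood",
    "run_mcmc",
    "diagnostics",
    "sample_posterior",
    "record_context",
]

_LOG10 = math.log(10.0)

#: parameter base name -> (class, entity kind, coordinate semantics)
PARAM_INFO = {
    "dlog10_ktrans_cmp": ("compound", "compound", "linear"),
    "dlog10_Klipw_cmp": ("compound", "compound", "linear"),
    "dlog10_Kinfw_cmp": ("compound", "compound", "linear"),
    "hSC_site": ("site", "site", "log10"),
    "Nf_site": ("site", "site", "log10"),
    "hSC_ind": ("individual", "individual", "log10"),
    "dlog10_ktrans_ind": ("individual", "individual", "linear"),
    "dlog10_Dinf_ind": ("individual", "individual", "linear"),
    "dlog10_fopen_ind": ("individual", "individual", "linear"),
    "log_nu2": ("nu", None, "ln_var"),
}


@dataclass(frozen=True)
class PriorSpec:
    """Bounded-uniform prior bounds in sampling coordinates.

    Multiplicative scalings are log-uniform on their stated support (uniform
    in log10 coordinates); additive perturbations are uniform; the error
    variance has p(nu^2) propto 1/nu^2, i.e. uniform in ln(nu^2), truncated
    to ``nu2_bounds``.
    """

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ValueError(f"prior bounds for {name} must be ordered")


def default_priors(nu2_bounds: tuple[float, float] = (1e-4, 1e2)) -> PriorSpec:
    """Priors on the inferred scalings (see docs/methods.md for the table)."""
    if not (0 < nu2_bounds[0] < nu2_bounds[1]):
        raise ValueError("nu^2 truncation bounds must be positive and ordered")
    l15 = math.log10(1.5)
    l125 = math.log10(1.25)
    return PriorSpec(
        bounds={
            "hSC_site": (-l15, l15),
            "hSC_ind": (-l15, l15),
            "dlog10_ktrans_cmp": (-0.54, 0.54),
            "dlog10_ktrans_ind": (-0.54, 0.54),
            "dlog10_Klipw_cmp": (-0.43, 0.43),
            "dlog10_Kinfw_cmp": (-1.0, 1.0),
            "dlog10_Dinf_ind": (-1.0, 1.0),
            "dlog10_fopen_ind": (-1.0, 1.0),
            "Nf_site": (-l125, l125),
            "log_nu2": (math.log(nu2_bounds[0]), math.log(nu2_bounds[1])),
        }
    )


# ---------------------------------------------------------------------------
# Parameter layout and vectors
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterLayout:
    """Flattened indexing of all scalings required by one data set."""

    compounds: tuple[str, ...]
    sites: tuple[str, ...]
    individuals: tuple[str, ...]
    entries: tuple[tuple[str, str | None], ...]  # (base name, entity)
    lo: np.ndarray
    hi: np.ndarray

    @classmethod
    def from_entities(
        cls,
        compounds,
        sites,
        individuals,
        priors: PriorSpec | None = None,
    ) -> "ParameterLayout":
        priors = priors or default_priors()
        entries: list[tuple[str, str | None]] = []
        for c in compounds:
            entries += [
                ("dlog10_ktrans_cmp", c),
                ("dlog10_Klipw_cmp", c),
                ("dlog10_Kinfw_cmp", c),
            ]
        for s in sites:
            entries += [("hSC_site", s), ("Nf_site", s)]
        for i in individuals:
            entries += [
                ("hSC_ind", i),
                ("dlog10_ktrans_ind", i),
                ("dlog10_Dinf_ind", i),
                ("dlog10_fopen_ind", i),
            ]
        entries.append(("log_nu2", None))
        lo = np.array([priors.bounds[b][0] for b, _ in entries])
        hi = np.array([priors.bounds[b][1] for b, _ in entries])
        return cls(
            compounds=tuple(compounds),
            sites=tuple(sites),
            individuals=tuple(individuals),
            entries=tuple(entries),
            lo=lo,
            hi=hi,
        )

    @classmethod
    def from_dataset(
        cls, data: TrainingDataSet, priors: PriorSpec | None = None
    ) -> "ParameterLayout":
        return cls.from_entities(
            data.compounds, data.sites, data.individuals, priors
        )

    @property
    def names(self) -> list[str]:
        return [
            base if ent is None else f"{base}[{ent}]" for base, ent in self.entries
        ]

    @property
    def dim(self) -> int:
        return len(self.entries)

    def index(self, base: str, entity: str | None = None) -> int:
        try:
            return self.entries.index((base, entity))
        except ValueError:
            raise KeyError(f"no parameter {base}[{entity}] in layout") from None

    def blocks(self) -> list[Block]:
        """One sampler block per parameter class and entity.

        Splitting each class by entity (per compound, per site, per donor)
        keeps proposal dimensionality low — the model's conditional structure
        couples parameters within an entity far more strongly than across
        entities."""
        by_key: dict[str, list[int]] = {}
        for j, (base, ent) in enumerate(self.entries):
            cls = PARAM_INFO[base][0]
            key = cls if ent is None else f"{cls}:{ent}"
            by_key.setdefault(key, []).append(j)
        return [Block(name=k, indices=tuple(v)) for k, v in by_key.items()]

    def mid_vector(self) -> np.ndarray:
        """Mid-support point (identity scalings, mid-range ln nu^2)."""
        return 0.5 * (self.lo + self.hi)

    def identity_vector(self, nu: float = 0.2) -> np.ndarray:
        """Identity scalings with the given error SD."""
        v = np.zeros(self.dim)
        v[self.index("log_nu2")] = math.log(nu**2)
        return v

    def in_support(self, values: np.ndarray) -> bool:
        v = np.atleast_2d(values)
        return bool(np.all(v >= self.lo) and np.all(v <= self.hi))

    def nu(self, values: np.ndarray) -> float:
        return math.exp(0.5 * values[self.index("log_nu2")])

    def scaling_set(
        self, values: np.ndarray, compound: str, site: str, individual: str
    ) -> ScalingSet:
        """Extract the ScalingSet relevant to one measurement context."""
        g = lambda base, ent: values[self.index(base, ent)]
        return ScalingSet(
            hSC_site=10.0 ** g("hSC_site", site),
            hSC_ind=10.0 ** g("hSC_ind", individual),
            dlog10_ktrans_cmp=g("dlog10_ktrans_cmp", compound),
            dlog10_ktrans_ind=g("dlog10_ktrans_ind", individual),
            dlog10_Klipw_cmp=g("dlog10_Klipw_cmp", compound),
            dlog10_Kinfw_cmp=g("dlog10_Kinfw_cmp", compound),
            dlog10_Dinf_ind=g("dlog10_Dinf_ind", individual),
            dlog10_fopen_ind=g("dlog10_fopen_ind", individual),
            Nf_site=10.0 ** g("Nf_site", site),
        )

    def set_scalings(
        self,
        values: np.ndarray,
        scalings: ScalingSet,
        compound: str,
        site: str,
        individual: str,
    ) -> np.ndarray:
        """Inverse of :meth:`scaling_set` (round-trip is lossless)."""
        v = values.copy()
        put = lambda base, ent, x: v.__setitem__(self.index(base, ent), x)
        put("hSC_site", site, math.log10(scalings.hSC_site))
        put("hSC_ind", individual, math.log10(scalings.hSC_ind))
        put("dlog10_ktrans_cmp", compound, scalings.dlog10_ktrans_cmp)
        put("dlog10_ktrans_ind", individual, scalings.dlog10_ktrans_ind)
        put("dlog10_Klipw_cmp", compound, scalings.dlog10_Klipw_cmp)
        put("dlog10_Kinfw_cmp", compound, scalings.dlog10_Kinfw_cmp)
        put("dlog10_Dinf_ind", individual, scalings.dlog10_Dinf_ind)
        put("dlog10_fopen_ind", individual, scalings.dlog10_fopen_ind)
        put("Nf_site", site, math.log10(scalings.Nf_site))
        return v


@dataclass(frozen=True)
class ParameterVector:
    """A point in the flattened parameter space of one data set."""

    layout: ParameterLayout
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != (self.layout.dim,):
            raise ValueError("values do not match layout dimension")

    @property
    def nu(self) -> float:
        return self.layout.nu(self.values)

    def scaling_set(self, compound: str, site: str, individual: str) -> ScalingSet:
        return self.layout.scaling_set(self.values, compound, site, individual)


# ---------------------------------------------------------------------------
# Vectorized model evaluation over a data set's records
# ---------------------------------------------------------------------------


def record_context(record: ExperimentRecord) -> ExperimentContext:
    return ExperimentContext(
        compound=record.compound,
        site=record.site,
        preparation=record.preparation,
        vehicle_pH=record.vehicle_pH,
        individual_id=record.individual_id,
    )


class DatasetModel:
    """Precompiled vectorized permeability evaluator for one data set.

    Evaluates the steady-state model for all records of a training data set
    at once; record-by-record equality with
    :func:`skinperm.core.total_permeability` is part of the test contract.
    """

    def __init__(
        self,
        data: TrainingDataSet,
        layout: ParameterLayout,
        registry: Registry | None = None,
    ) -> None:
        reg = registry if registry is not None else default_registry()
        self.data = data
        self.layout = layout
        recs = data.records
        n = len(recs)
        self.observed = np.array([r.P_mean for r in recs])
        self.log_obs = np.log(self.observed)

        c_pos = {c: k for k, c in enumerate(layout.compounds)}
        s_pos = {s: k for k, s in enumerate(layout.sites)}
        i_pos = {i: k for k, i in enumerate(layout.individuals)}
        self.c_idx = np.array([c_pos[r.compound] for r in recs])
        self.s_idx = np.array([s_pos[r.site] for r in recs])
        self.i_idx = np.array([i_pos[r.individual_id] for r in recs])

        fixed0 = reg.fixed_params("heat-separated")
        comps = [reg.compound(r.compound) for r in recs]
        sites = [reg.site(r.site) for r in recs]
        self.MW = np.array([c.MW for c in comps])
        self.fnon = np.array(
            [core.fraction_nonionized(c.pKa, r.vehicle_pH) for c, r in zip(comps, recs)]
        )
        q = reg.qspr
        self.l10_ktrans_nom = np.array(
            [
                core.nominal_log10_ktrans(
                    c.MW, q["ktrans"]["intercept"], q["ktrans"]["slope"]
                )
                for c in comps
            ]
        )
        self.l10_Klipw_nom = np.array(
            [
                core.nominal_log10_Klipw(
                    c.logKow, q["klipw"]["slope"], q["klipw"]["intercept_factor"]
                )
                for c in comps
            ]
        )
        self.l10_Kinfw_nom = -np.log10(self.fnon)
        self.l10_Dinf_nom = np.array(
            [core.nominal_log10_Dinf(c.MW, fixed0.ADaq, fixed0.BDaq) for c in comps]
        )
        self.hSC_nom_cm = np.array([s.hSC_nom for s in sites]) * 1e-4
        self.Nf_nom = np.array([s.Nf_nom for s in sites])
        self.r1_cm = np.array([s.r1_over_r0 for s in sites]) * fixed0.r0 * 1e-4
        self.hde_cm = np.array(
            [reg.fixed_params(r.preparation).hde for r in recs]
        ) * 1e-4
        self.fixed = fixed0
        # index arrays into the parameter vector, one entry per record
        L = layout
        self.j = {
            base: np.array(
                [
                    L.index(base, {"compound": r.compound, "site": r.site,
                                   "individual": r.individual_id}[PARAM_INFO[base][1]])
                    for r in recs
                ]
            )
            for base in PARAM_INFO
            if base != "log_nu2"
        }
        self.j_nu = L.index("log_nu2")

        # precompiled coefficients for the fast prediction path: every
        # record's permeability reduces to
        #   P = 10^(inf_e + s_inf)/hSC + series(lip + pore, viable)
        # with hSC = hSC_nom * 10^(site+ind) and lip = lip_coef*10^(s_lip)/hSC
        fx = fixed0
        r_sol = core.solute_radius_cm(self.MW, fx.solute_density)
        lam = r_sol / (fx.r2 * 1e-7)
        pore_area = fx.Np * math.pi * (fx.r2 * 1e-7) ** 2 * core._renkin_hindrance(lam)
        daq = 10.0 ** self.l10_Dinf_nom
        self._pore_num = pore_area * daq  # / hSC
        self._lip_e0 = (
            np.log10(self.fnon)
            + self.l10_ktrans_nom
            + self.l10_Klipw_nom
            + math.log10(fx.my * 1e-4 / fx.bilayers_per_cc_layer)
        )
        self._inf_e0 = (
            np.log10(self.Nf_nom * fx.fopen_nom * math.pi * (fx.r0 * 1e-4) * self.r1_cm)
            + np.log10(self.fnon)
            + self.l10_Kinfw_nom
            + self.l10_Dinf_nom
        )
        thick = fx.hed * 1e-4 + self.hde_cm
        self._viable = fx.K_viable_w * (daq / fx.viable_tortuosity) / thick

    def effective(self, values: np.ndarray) -> EffectiveParams:
        v = np.asarray(values)
        fx = self.fixed
        hSC = (
            self.hSC_nom_cm
            * 10.0 ** v[self.j["hSC_site"]]
            * 10.0 ** v[self.j["hSC_ind"]]
        )
        my = fx.my * 1e-4
        return EffectiveParams(
            hSC=hSC,
            my=my,
            ktrans=10.0
            ** (
                self.l10_ktrans_nom
                + v[self.j["dlog10_ktrans_cmp"]]
                + v[self.j["dlog10_ktrans_ind"]]
            ),
            Klipw=10.0 ** (self.l10_Klipw_nom + v[self.j["dlog10_Klipw_cmp"]]),
            Kinfw=10.0 ** (self.l10_Kinfw_nom + v[self.j["dlog10_Kinfw_cmp"]]),
            Dinf=10.0 ** (self.l10_Dinf_nom + v[self.j["dlog10_Dinf_ind"]]),
            Daq=10.0 ** self.l10_Dinf_nom,
            fopen=fx.fopen_nom * 10.0 ** v[self.j["dlog10_fopen_ind"]],
            Nf=self.Nf_nom * 10.0 ** v[self.j["Nf_site"]],
            r0=fx.r0 * 1e-4,
            r1=self.r1_cm,
            r2=fx.r2 * 1e-7,
            Np=fx.Np,
            hed=fx.hed * 1e-4,
            hde=self.hde_cm,
            K_viable_w=fx.K_viable_w,
            viable_tortuosity=fx.viable_tortuosity,
            r_solute=core.solute_radius_cm(self.MW, fx.solute_density),
            n_bilayers=fx.bilayers_per_cc_layer * hSC / my,
        )

    def predict(self, values: np.ndarray) -> np.ndarray:
        """Model permeability for every record, cm/s.

        Algebraically identical to evaluating
        :func:`skinperm.core.total_permeability` record by record (asserted
        in the test suite); reduced to three exponentials for sampler speed.
        """
        v = np.asarray(values)
        j = self.j
        hSC = self.hSC_nom_cm * 10.0 ** (v[j["hSC_site"]] + v[j["hSC_ind"]])
        lip = (
            10.0
            ** (
                self._lip_e0
                + v[j["dlog10_ktrans_cmp"]]
                + v[j["dlog10_ktrans_ind"]]
                + v[j["dlog10_Klipw_cmp"]]
            )
            / hSC
        )
        pore = self._pore_num / hSC
        inf = (
            10.0
            ** (
                self._inf_e0
                + v[j["dlog10_Kinfw_cmp"]]
                + v[j["dlog10_Dinf_ind"]]
                + v[j["dlog10_fopen_ind"]]
                + v[j["Nf_site"]]
            )
            / hSC
        )
        sc = lip + pore
        return inf + sc * self._viable / (sc + self._viable)


# ---------------------------------------------------------------------------
# Posterior pieces
# ---------------------------------------------------------------------------


def log_prior(values: np.ndarray, layout: ParameterLayout) -> float:
    """Unnormalized log prior: flat in sampling coordinates inside support."""
    return 0.0 if layout.in_support(np.asarray(values)) else -math.inf


def log_likelihood(values: np.ndarray, model: DatasetModel) -> float:
    """Log-normal measurement likelihood with shared variance nu^2."""
    v = np.asarray(values)
    nu2 = math.exp(v[model.j_nu])
    try:
        f = model.predict(v)
    except ValueError as exc:
        bad = ", ".join(r.experiment_name for r in model.data.records)
        raise ValueError(f"model evaluation failed for records [{bad}]: {exc}")
    resid = np.log(f) - model.log_obs
    n = resid.size
    return float(-0.5 * n * math.log(2.0 * math.pi * nu2) - resid @ resid / (2.0 * nu2))


@dataclass
class PosteriorDraws:
    """Post-burn-in joint posterior samples with chain metadata."""

    layout: ParameterLayout
    samples: np.ndarray  # (n_chains, n_kept, dim)
    accept_rates: dict[str, np.ndarray]
    seed: int
    config: MCMCConfig
    adaptation_history: dict = field(default_factory=dict)
    dataset_id: str | None = None

    @property
    def n_chains(self) -> int:
        return self.samples.shape[0]

    def flat(self) -> np.ndarray:
        return self.samples.reshape(-1, self.layout.dim)

    def to_frame(self) -> pd.DataFrame:
        nch, nit, dim = self.samples.shape
        df = pd.DataFrame(self.flat(), columns=self.layout.names)
        df.insert(0, "iteration", np.tile(np.arange(nit), nch))
        df.insert(0, "chain", np.repeat(np.arange(nch), nit))
        return df

    def marginal(self, base: str, entity: str | None = None) -> np.ndarray:
        return self.flat()[:, self.layout.index(base, entity)]

    def save(self, directory) -> None:
        """Write chains as tabular text plus a JSON metadata sidecar."""
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(d / "chains.csv", index=False)
        meta = {
            "compounds": list(self.layout.compounds),
            "sites": list(self.layout.sites),
            "individuals": list(self.layout.individuals),
            "seed": self.seed,
            "n_chains": int(self.samples.shape[0]),
            "n_kept": int(self.samples.shape[1]),
            "dataset_id": self.dataset_id,
            "accept_rates": {k: v.tolist() for k, v in self.accept_rates.items()},
        }
        (d / "meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, directory, priors: PriorSpec | None = None) -> "PosteriorDraws":
        import json
        from pathlib import Path

        d = Path(directory)
        meta = json.loads((d / "meta.json").read_text())
        layout = ParameterLayout.from_entities(
            meta["compounds"], meta["sites"], meta["individuals"], priors
        )
        df = pd.read_csv(d / "chains.csv")
        vals = df[layout.names].to_numpy()
        samples = vals.reshape(meta["n_chains"], meta["n_kept"], layout.dim)
        return cls(
            layout=layout,
            samples=samples,
            accept_rates={k: np.asarray(v) for k, v in meta["accept_rates"].items()},
            seed=meta["seed"],
            config=MCMCConfig(seed=meta["seed"]),
            dataset_id=meta.get("dataset_id"),
        )


def run_mcmc(
    data: TrainingDataSet,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    registry: Registry | None = None,
    prior_only: bool = False,
) -> PosteriorDraws:
    """Sample the joint posterior for one training data set.

    ``prior_only=True`` drops the likelihood term (for prior-predictive and
    sampler-validation runs).  Identical seed/config give identical chains.
    """
    if data is None or not data.records:
        raise ValueError("data set is empty")
    priors = priors or default_priors()
    config = config or MCMCConfig()
    layout = ParameterLayout.from_dataset(data, priors)
    model = DatasetModel(data, layout, registry)

    j_nu = layout.index("log_nu2")
    nu2_lo, nu2_hi = math.exp(layout.lo[j_nu]), math.exp(layout.hi[j_nu])

    if prior_only:
        log_post = lambda v: log_prior(v, layout)

        def nu_gibbs(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
            return np.array([rng.uniform(layout.lo[j_nu], layout.hi[j_nu])])

    else:

        def log_post(v: np.ndarray) -> float:
            lp = log_prior(v, layout)
            if not np.isfinite(lp):
                return -math.inf
            return lp + log_likelihood(v, model)

        from scipy.stats import invgamma

        n_obs = len(data.records)

        def nu_gibbs(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
            # nu^2 | residuals is inverse-gamma under the 1/nu^2 prior; draw
            # it exactly (truncated to the prior bounds) — this decouples the
            # error variance from the scaling parameters and avoids the
            # small-variance funnel a Metropolis step mixes through slowly
            resid = np.log(model.predict(x)) - model.log_obs
            ssr = max(float(resid @ resid), 1e-300)
            a, scale = n_obs / 2.0, ssr / 2.0
            c_lo = invgamma.cdf(nu2_lo, a, scale=scale)
            c_hi = invgamma.cdf(nu2_hi, a, scale=scale)
            u = rng.uniform(c_lo, c_hi)
            nu2 = float(
                np.clip(invgamma.ppf(u, a, scale=scale), nu2_lo, nu2_hi)
            )
            return np.array([math.log(nu2)])

    result: ChainResult = run_block_mh(
        log_post,
        layout.lo,
        layout.hi,
        layout.blocks(),
        config,
        gibbs={"nu": nu_gibbs},
    )
    return PosteriorDraws(
        layout=layout,
        samples=result.samples,
        accept_rates=result.accept_rates,
        seed=config.seed,
        config=config,
        adaptation_history=result.adaptation_history,
        dataset_id=data.dataset_id,
    )


def diagnostics(
    draws: PosteriorDraws, rhat_threshold: float = 1.05, ess_floor: float = 100.0
) -> pd.DataFrame:
    """Per-parameter split R-hat and bulk ESS, with threshold flags."""
    rows = []
    single = draws.n_chains < 2
    if single:
        warnings.warn("single chain: R-hat omitted", stacklevel=2)
    for j, name in enumerate(draws.layout.names):
        chains = draws.samples[:, :, j]
        rhat = np.nan if single else split_rhat(chains)
        ess = ess_bulk(chains)
        rows.append(
            {
                "parameter": name,
                "rhat": rhat,
                "ess": ess,
                "flagged": (not single and rhat > rhat_threshold) or ess < ess_floor,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["accept_rates"] = {
        k: v.tolist() for k, v in draws.accept_rates.items()
    }
    return df


def sample_posterior(
    draws: PosteriorDraws, n: int, seed: int = 0
) -> list[ParameterVector]:
    """Uniform resampling (with replacement) of joint post-burn-in draws."""
    if n <= 0:
        raise ValueError("n must be positive")
    flat = draws.flat()
    if flat.shape[0] == 0:
        raise ValueError("no stored draws")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, flat.shape[0], size=n)
    return [ParameterVector(draws.layout, flat[i].copy()) for i in idx]
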