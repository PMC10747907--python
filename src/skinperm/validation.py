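"""Posterior-predictive validation, extrapolation and design comparison.

Given posterior draws trained on one data set, this module generates:

* an internal visual-predictive-check (VPC): per-record predictive
  distributions using each record's own compound/site/individual scalings,
  with the measurement-noise term included;
* external validation 1: compound x site predictions at vehicle pH 7.4 on
  heat-separated epidermis, pooling the trained donors' individual scalings,
  with cross-compound/cross-site substitution where the training data lack
  the target compound or site;
* external validation 2: predictions over the variable-pH measurement grid
  on dermatomed thigh skin, using the pH-9.37 donor's individual scalings
  when that donor was trained and the full donor pool otherwise;
* pathway-specific posterior summaries (trans-bilayer permeability relative
  to water, infundibular permeability at a reference context) and a
  design-comparison table across training groups.

Every prediction is generated through
:func:`skinperm.core.total_permeability` — there is no separate prediction
code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from skinperm import core
from skinperm.core import ExperimentContext, ScalingSet
from skinperm.datasets import TrainingDataSet, load_reference_measurements
from skinperm.inference import (
    ParameterVector,
    PosteriorDraws,
    record_context,
    sample_posterior,
)

__all__ = [
    "PredictionDistribution",
    "PathwaySummary",
    "REFERENCE_CONTEXT",
    "internal_vpc",
    "extrapolate_cross_compound",
    "external_validation_1",
    "external_validation_2",
    "pathway_summaries",
    "log10_ktrans_w_samples",
    "design_comparison_report",
]

#: reference context for pathway-specific summaries
REFERENCE_CONTEXT = ExperimentContext(
    compound="fentanyl",
    site="thigh",
    preparation="heat-separated",
    vehicle_pH=7.40,
)

DEFAULT_QUANTILES = (0.025, 0.25, 0.5, 0.75, 0.975)


@dataclass
class PredictionDistribution:
    """Predictive samples of P_tot/w (cm/s) for one context or scenario."""

    label: str
    context: ExperimentContext | None
    samples: np.ndarray
    quantile_levels: tuple[float, ...] = DEFAULT_QUANTILES

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if np.any(self.samples <= 0):
            raise ValueError("predictive permeability samples must be > 0")
        if list(self.quantile_levels) != sorted(self.quantile_levels):
            raise ValueError("quantile levels must be monotone")

    @property
    def quantiles(self) -> dict[float, float]:
        qs = np.quantile(self.samples, self.quantile_levels)
        return dict(zip(self.quantile_levels, qs.tolist()))

    @property
    def median(self) -> float:
        return float(np.median(self.samples))

    def central_interval(self, level: float = 0.95) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.samples, [a, 1.0 - a])
        return float(lo), float(hi)


@dataclass
class PathwaySummary:
    """Pathway-specific posterior samples for one compound.

    ``log10_ktrans_w`` is the compound-level trans-bilayer permeability
    relative to water (nominal ktrans and Klip/w plus their compound
    perturbations); ``log10_Pinf_w`` is the infundibular permeability at the
    reference context, pooled over the trained individuals from the same
    joint resample.
    """

    compound: str
    log10_ktrans_w: np.ndarray
    log10_Pinf_w: np.ndarray
    reference_context: ExperimentContext = REFERENCE_CONTEXT

    def __post_init__(self) -> None:
        if len(self.log10_ktrans_w) != len(self.log10_Pinf_w):
            raise ValueError(
                "pathway sample vectors must come from the same joint resample"
            )


def _predict(context: ExperimentContext, scalings: ScalingSet) -> float:
    # module-attribute call so the one-engine contract is observable in tests
    return core.total_permeability(context, scalings).P_tot_w


# ---------------------------------------------------------------------------
# Internal validation (VPC)
# ---------------------------------------------------------------------------


def internal_vpc(
    draws: PosteriorDraws,
    dataset: TrainingDataSet,
    n_samples: int = 400,
    include_noise: bool = True,
    seed: int = 0,
    interval: float = 0.95,
) -> tuple[list[PredictionDistribution], pd.DataFrame]:
    """Per-record posterior-predictive distributions and coverage table.

    For each record the model is re-simulated with that record's own
    compound/site/individual scalings from the joint posterior; with
    ``include_noise`` the log-normal measurement error (per-draw nu) is
    added, making the predictive comparable to a noisy observation.
    """
    layout = draws.layout
    for r in dataset.records:
        if r.individual_id not in layout.individuals:
            raise ValueError(
                f"record {r.experiment_name}: individual {r.individual_id} "
                "absent from posterior draws"
            )
    vecs = sample_posterior(draws, n_samples, seed=seed)
    rng = np.random.default_rng(seed + 1)
    eps = rng.standard_normal((n_samples, len(dataset.records)))

    dists: list[PredictionDistribution] = []
    rows = []
    for k, rec in enumerate(dataset.records):
        ctx = record_context(rec)
        vals = np.empty(n_samples)
        for m, pv in enumerate(vecs):
            s = pv.scaling_set(rec.compound, rec.site, rec.individual_id)
            f = _predict(ctx, s)
            if include_noise:
                f *= np.exp(pv.nu * eps[m, k])
            vals[m] = f
        dist = PredictionDistribution(rec.experiment_name, ctx, vals)
        dists.append(dist)
        lo, hi = dist.central_interval(interval)
        rows.append(
            {
                "experiment": rec.experiment_name,
                "observed": rec.P_mean,
                "pred_median": dist.median,
                "pred_lo": lo,
                "pred_hi": hi,
                "inside": bool(lo <= rec.P_mean <= hi),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["coverage"] = float(table["inside"].mean())
    return dists, table


# ---------------------------------------------------------------------------
# Cross-compound / cross-site extrapolation
# ---------------------------------------------------------------------------


def _source_entity(available: Sequence[str], wanted: str) -> str:
    """Direct when trained; otherwise substitute the trained entity's draws."""
    if wanted in available:
        return wanted
    if len(available) == 1:
        return available[0]
    raise ValueError(
        f"{wanted!r} untrained and substitution ambiguous among {available}"
    )


def extrapolate_cross_compound(
    draws: PosteriorDraws,
    source_compound: str,
    target_compound: str,
    context: ExperimentContext,
    n_samples: int = 400,
    seed: int = 0,
) -> PredictionDistribution:
    """Predict a target compound using a source compound's scaling draws.

    The source compound's inferred compound-specific perturbations are
    applied to the target compound's nominal parameters; site and individual
    draws stay joint.  With target == source this reduces exactly to direct
    prediction.
    """
    layout = draws.layout
    if source_compound not in layout.compounds:
        raise ValueError(f"source compound {source_compound!r} not in draws")
    site_src = _source_entity(layout.sites, context.site)
    vecs = sample_posterior(draws, n_samples, seed=seed)
    rng = np.random.default_rng(seed + 1)
    individuals = layout.individuals
    ind_pick = rng.integers(0, len(individuals), size=n_samples)
    vals = np.empty(n_samples)
    for m, pv in enumerate(vecs):
        s = pv.scaling_set(source_compound, site_src, individuals[ind_pick[m]])
        vals[m] = _predict(
            ExperimentContext(
                compound=target_compound,
                site=context.site,
                preparation=context.preparation,
                vehicle_pH=context.vehicle_pH,
                individual_id=context.individual_id,
            ),
            s,
        )
    return PredictionDistribution(
        f"{target_compound}|{source_compound}-draws", context, vals
    )


# ---------------------------------------------------------------------------
# External validations
# ---------------------------------------------------------------------------

EV1_SCENARIOS = tuple(
    (c, s) for c in ("fentanyl", "sufentanil") for s in ("abdomen", "thigh")
)


def external_validation_1(
    draws_per_dataset: Mapping[str, PosteriorDraws],
    n_samples: int = 400,
    seed: int = 0,
) -> pd.DataFrame:
    """Compound x site predictions at pH 7.4, heat-separated epidermis.

    For each data set and each of the four compound/site scenarios, the
    posterior is resampled jointly; each draw is paired with one trained
    donor's individual scalings, and untrained compounds or sites borrow the
    trained entity's draws (correlation-similarity substitution).
    """
    rows = []
    for ds_id, draws in draws_per_dataset.items():
        layout = draws.layout
        vecs = sample_posterior(draws, n_samples, seed=seed)
        rng = np.random.default_rng(seed + 1)
        ind_pick = rng.integers(0, len(layout.individuals), size=n_samples)
        for compound, site in EV1_SCENARIOS:
            cmp_src = _source_entity(layout.compounds, compound)
            site_src = _source_entity(layout.sites, site)
            ctx = ExperimentContext(
                compound=compound,
                site=site,
                preparation="heat-separated",
                vehicle_pH=7.40,
            )
            vals = np.empty(n_samples)
            for m, pv in enumerate(vecs):
                ind = layout.individuals[ind_pick[m]]
                vals[m] = _predict(ctx, pv.scaling_set(cmp_src, site_src, ind))
            dist = PredictionDistribution(f"{ds_id}:{compound}:{site}", ctx, vals)
            lo, hi = dist.central_interval(0.95)
            rows.append(
                {
                    "dataset": ds_id,
                    "compound": compound,
                    "site": site,
                    "pred_median": dist.median,
                    "pred_lo": lo,
                    "pred_hi": hi,
                }
            )
    out = pd.DataFrame(rows)
    obs = _observed_ranges_ph74()
    return out.merge(obs, on=["compound", "site"], how="left")


def _observed_ranges_ph74() -> pd.DataFrame:
    recs = [
        r
        for r in load_reference_measurements()
        if r.preparation == "heat-separated"
    ]
    rows = []
    for compound in ("fentanyl", "sufentanil"):
        for site in ("thigh", "abdomen"):
            vals = [
                r.P_mean for r in recs if r.compound == compound and r.site == site
            ]
            rows.append(
                {
                    "compound": compound,
                    "site": site,
                    "obs_min": min(vals),
                    "obs_median": float(np.median(vals)),
                    "obs_max": max(vals),
                }
            )
    return pd.DataFrame(rows)


def external_validation_2(
    draws_per_dataset: Mapping[str, PosteriorDraws],
    training_sets: Mapping[str, TrainingDataSet] | None = None,
    n_samples: int = 400,
    seed: int = 0,
) -> pd.DataFrame:
    """Predictions over the variable-pH grid (dermatomed thigh skin).

    The validation grid is the printed pH series minus any experiment used in
    training the given data set.  Individual scalings come from the pH-9.37
    donor where trained (cross-over high-pH groups) and from the full donor
    pool otherwise.
    """
    ph_records = [
        r for r in load_reference_measurements() if r.preparation == "dermatomed"
    ]
    trained_names: dict[str, set[str]] = {}
    if training_sets:
        for ds_id, ds in training_sets.items():
            trained_names[ds_id] = {r.experiment_name for r in ds.records}
    rows = []
    for ds_id, draws in draws_per_dataset.items():
        layout = draws.layout
        vecs = sample_posterior(draws, n_samples, seed=seed)
        rng = np.random.default_rng(seed + 1)
        if "D12" in layout.individuals:
            ind_pool = ("D12",)
        else:
            warnings.warn(
                f"{ds_id}: pH-series donor absent from draws; "
                "sampling individual scalings from all trained donors"
            )
            ind_pool = layout.individuals
        ind_pick = rng.integers(0, len(ind_pool), size=n_samples)
        site_src = _source_entity(layout.sites, "thigh")
        for rec in ph_records:
            if rec.experiment_name in trained_names.get(ds_id, set()):
                continue
            cmp_src = _source_entity(layout.compounds, rec.compound)
            ctx = record_context(rec)
            vals = np.empty(n_samples)
            for m, pv in enumerate(vecs):
                ind = ind_pool[ind_pick[m]]
                vals[m] = _predict(ctx, pv.scaling_set(cmp_src, site_src, ind))
            dist = PredictionDistribution(
                f"{ds_id}:{rec.experiment_name}", ctx, vals
            )
            lo, hi = dist.central_interval(0.95)
            rows.append(
                {
                    "dataset": ds_id,
                    "experiment": rec.experiment_name,
                    "compound": rec.compound,
                    "vehicle_pH": rec.vehicle_pH,
                    "observed": rec.P_mean,
                    "pred_median": dist.median,
                    "pred_lo": lo,
                    "pred_hi": hi,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pathway-specific posterior summaries and design comparison
# ---------------------------------------------------------------------------


def log10_ktrans_w_samples(
    draws: PosteriorDraws, compound: str, registry=None
) -> np.ndarray:
    """Compound-level log10 of ktrans * Klip/w from the joint chain."""
    reg = registry if registry is not None else core.default_registry()
    c = reg.compound(compound)
    nom = core.nominal_log10_ktrans(c.MW) + core.nominal_log10_Klipw(c.logKow)
    return (
        nom
        + draws.marginal("dlog10_ktrans_cmp", compound)
        + draws.marginal("dlog10_Klipw_cmp", compound)
    )


def pathway_summaries(
    draws: PosteriorDraws,
    reference_context: ExperimentContext = REFERENCE_CONTEXT,
    n_samples: int = 400,
    seed: int = 0,
) -> list[PathwaySummary]:
    """Posterior distributions of ktrans/w and Pinf/w per trained compound.

    Both quantities are derived from the same joint resample, preserving the
    chain's cross-parameter correlations; Pinf/w is evaluated through the
    full model at the reference context, pooling trained individuals.
    """
    layout = draws.layout
    vecs = sample_posterior(draws, n_samples, seed=seed)
    rng = np.random.default_rng(seed + 1)
    ind_pick = rng.integers(0, len(layout.individuals), size=n_samples)
    out = []
    for compound in layout.compounds:
        reg = core.default_registry()
        c = reg.compound(compound)
        nom = core.nominal_log10_ktrans(c.MW) + core.nominal_log10_Klipw(c.logKow)
        kt = np.empty(n_samples)
        pinf = np.empty(n_samples)
        for m, pv in enumerate(vecs):
            ind = layout.individuals[ind_pick[m]]
            site_src = _source_entity(layout.sites, reference_context.site)
            s = pv.scaling_set(compound, site_src, ind)
            kt[m] = nom + s.dlog10_ktrans_cmp + s.dlog10_Klipw_cmp
            ctx = ExperimentContext(
                compound=compound,
                site=reference_context.site,
                preparation=reference_context.preparation,
                vehicle_pH=reference_context.vehicle_pH,
                individual_id=ind,
            )
            pinf[m] = np.log10(core.total_permeability(ctx, s).P_inf_w)
        out.append(
            PathwaySummary(
                compound=compound,
                log10_ktrans_w=kt,
                log10_Pinf_w=pinf,
                reference_context=reference_context,
            )
        )
    return out


def design_comparison_report(
    group_results: Mapping[str, Sequence[PathwaySummary]],
) -> pd.DataFrame:
    """Tabulate per-data-set compound divergences and interval widths.

    ``group_results`` maps a data-set label to its pathway summaries.  For
    two-compound data sets the report includes the absolute between-compound
    difference of median log10 ktrans/w and median log10 Pinf/w; interval
    widths are central-90% widths averaged over compounds.
    """
    if not group_results:
        raise ValueError("need results for at least one data set")
    rows = []
    for label, summaries in group_results.items():
        med_kt = {s.compound: float(np.median(s.log10_ktrans_w)) for s in summaries}
        med_pi = {s.compound: float(np.median(s.log10_Pinf_w)) for s in summaries}
        widths = [
            float(np.diff(np.quantile(s.log10_ktrans_w, [0.05, 0.95]))[0])
            for s in summaries
        ]
        row = {
            "dataset": label,
            "n_compounds": len(summaries),
            "mean_width90_log10_ktrans_w": float(np.mean(widths)),
        }
        if len(summaries) == 2:
            (c1, c2) = sorted(med_kt)
            row["divergence_log10_ktrans_w"] = abs(med_kt[c1] - med_kt[c2])
            row["divergence_log10_Pinf_w"] = abs(med_pi[c1] - med_pi[c2])
        rows.append(row)
    return pd.DataFrame(rows)
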