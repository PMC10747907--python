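"""Synthetic permeability studies with known ground truth.

Generates steady-state permeability "measurements" under the same
multiplicative log-normal error model assumed by the likelihood:
``log d = log f(truth) + eps`` with ``eps ~ Normal(0, nu^2)``.  Study designs
mirror the reference experiment groups (cross-over/parallel, common/varied
pH, single/both sites) but use synthetic donor labels (SD01, ...) so that
generated studies can never be confused with the packaged reference tables.

The generated data sets satisfy the same group invariants as the reference
training data sets (shared validator), so every pipeline stage — inference,
validation, design comparison — runs on synthetic studies unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from skinperm import core
from skinperm.core import ExperimentContext
from skinperm.datasets import (
    ExperimentRecord,
    TrainingDataSet,
    validate_group_constraints,
)
from skinperm.inference import (
    ParameterLayout,
    ParameterVector,
    PosteriorDraws,
    PriorSpec,
    default_priors,
)

__all__ = [
    "SyntheticStudySpec",
    "design_table",
    "generate_study",
    "draw_truth_from_priors",
    "recovery_report",
]

_SYN_PH_HIGH = 9.37
_SYN_PH_BASE = 7.40


def design_table(design: str) -> pd.DataFrame:
    """Context table (donor x compound x site x pH x preparation) for a
    named design emulating one reference group's structure.

    A/B: cross-over, 3 thigh + 3 abdomen donors (B: one thigh donor at the
    high pH on dermatomed skin); C: single-site cross-over (C1 abdomen, C2
    thigh with a high-pH donor); D: single-compound, twelve donors, one at
    high pH; E: parallel, thigh donors on one compound (one at high pH) and
    abdomen donors on the other.
    """
    both = ("fentanyl", "sufentanil")
    rows: list[dict] = []

    def add(donor, site, compound, ph=_SYN_PH_BASE, prep="heat-separated"):
        rows.append(
            {
                "individual_id": donor,
                "site": site,
                "compound": compound,
                "vehicle_pH": ph,
                "preparation": prep,
            }
        )

    d = design.upper()
    if d in ("A", "B"):
        for k in range(1, 4):
            site = "thigh"
            donor = f"SD{k:02d}"
            if d == "B" and k == 3:
                for c in both:
                    add(donor, site, c, _SYN_PH_HIGH, "dermatomed")
            else:
                for c in both:
                    add(donor, site, c)
        for k in range(4, 7):
            for c in both:
                add(f"SD{k:02d}", "abdomen", c)
    elif d in ("C1", "C2"):
        site = "abdomen" if d == "C1" else "thigh"
        for k in range(1, 7):
            donor = f"SD{k:02d}"
            if d == "C2" and k == 6:
                for c in both:
                    add(donor, site, c, _SYN_PH_HIGH, "dermatomed")
            else:
                for c in both:
                    add(donor, site, c)
    elif d in ("D1", "D2"):
        compound = "fentanyl" if d == "D1" else "sufentanil"
        for k in range(1, 13):
            donor = f"SD{k:02d}"
            if k <= 6:
                if k == 6:
                    add(donor, "thigh", compound, _SYN_PH_HIGH, "dermatomed")
                else:
                    add(donor, "thigh", compound)
            else:
                add(donor, "abdomen", compound)
    elif d in ("E", "E1", "E2"):
        cmp_thigh, cmp_abd = both if d in ("E", "E1") else both[::-1]
        for k in range(1, 7):
            donor = f"SD{k:02d}"
            if k == 6:
                add(donor, "thigh", cmp_thigh, _SYN_PH_HIGH, "dermatomed")
            else:
                add(donor, "thigh", cmp_thigh)
        for k in range(7, 13):
            add(f"SD{k:02d}", "abdomen", cmp_abd)
    else:
        raise ValueError(f"unknown design {design!r}")
    return pd.DataFrame(rows)


@dataclass
class SyntheticStudySpec:
    """Specification of one synthetic permeability study.

    ``design`` is a named group-style design label or a custom context table
    with columns individual_id/site/compound/vehicle_pH/preparation;
    ``truth`` (optional) is a ParameterVector over the design's entities —
    drawn from the mid-prior by default; ``nu`` is the relative error SD on
    the natural-log scale.
    """

    design: str | pd.DataFrame
    nu: float = 0.2
    n_replicates: int = 4
    seed: int = 0
    truth: ParameterVector | None = None
    priors: PriorSpec = field(default_factory=default_priors)

    def __post_init__(self) -> None:
        if not (self.nu > 0):
            raise ValueError("nu must be > 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def table(self) -> pd.DataFrame:
        if isinstance(self.design, str):
            return design_table(self.design)
        required = {"individual_id", "site", "compound", "vehicle_pH", "preparation"}
        missing = required - set(self.design.columns)
        if missing:
            raise ValueError(f"custom design table missing columns {sorted(missing)}")
        return self.design.copy()


def _layout_for_table(table: pd.DataFrame, priors: PriorSpec) -> ParameterLayout:
    return ParameterLayout.from_entities(
        tuple(sorted(table["compound"].unique())),
        tuple(sorted(table["site"].unique())),
        tuple(sorted(table["individual_id"].unique())),
        priors,
    )


def draw_truth_from_priors(
    priors: PriorSpec,
    layout: ParameterLayout,
    seed: int = 0,
    shrink: float = 1.0,
) -> ParameterVector:
    """Independent per-parameter draws from the prior distributions.

    ``shrink`` < 1 draws from the central fraction of each support (recovery
    studies default to mid-support truths to avoid boundary-biased coverage);
    ``shrink=1`` recovers the full prior.
    """
    if not (0.0 < shrink <= 1.0):
        raise ValueError("shrink must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    mid = 0.5 * (layout.lo + layout.hi)
    half = 0.5 * (layout.hi - layout.lo) * shrink
    values = mid + (2.0 * rng.random(layout.dim) - 1.0) * half
    return ParameterVector(layout, values)


def generate_study(spec: SyntheticStudySpec) -> tuple[TrainingDataSet, ParameterVector]:
    """Generate one synthetic study: records plus the generating truth.

    Each record's mean permeability is the noise-free model output at the
    truth multiplied by exp(eps), eps ~ Normal(0, nu^2); deterministic per
    seed.  Named designs are checked against the shared group validator.
    """
    table = spec.table()
    layout = _layout_for_table(table, spec.priors)
    if spec.truth is None:
        truth = draw_truth_from_priors(spec.priors, layout, seed=spec.seed, shrink=0.5)
    else:
        if spec.truth.layout.entries != layout.entries:
            raise ValueError("truth layout does not match the design's entities")
        truth = spec.truth
    tvals = truth.values.copy()
    tvals[layout.index("log_nu2")] = 2.0 * np.log(spec.nu)
    truth = ParameterVector(layout, tvals)

    rng = np.random.default_rng(spec.seed + 1)
    records = []
    for k, row in enumerate(table.itertuples(index=False)):
        ctx = ExperimentContext(
            compound=row.compound,
            site=row.site,
            preparation=row.preparation,
            vehicle_pH=float(row.vehicle_pH),
            individual_id=row.individual_id,
        )
        s = truth.scaling_set(row.compound, row.site, row.individual_id)
        try:
            f = core.total_permeability(ctx, s).P_tot_w
        except ValueError as exc:
            raise ValueError(
                f"model failure at truth for record {k} "
                f"({row.compound}, {row.site}, pH {row.vehicle_pH}): {exc}"
            )
        eps = float(rng.standard_normal())
        p = f * np.exp(spec.nu * eps)
        records.append(
            ExperimentRecord(
                experiment_name=f"SYN{k + 1:02d}",
                individual_id=row.individual_id,
                site=row.site,
                preparation=row.preparation,
                vehicle_pH=float(row.vehicle_pH),
                compound=row.compound,
                n_replicates=spec.n_replicates,
                P_mean=float(p),
                P_sd=float(p) * spec.nu,
            )
        )
    if isinstance(spec.design, str):
        group = spec.design.upper()[0]
        ds = TrainingDataSet(group, f"SYN-{spec.design.upper()}", tuple(records))
        validate_group_constraints(ds)
    else:
        ds = TrainingDataSet("A", "SYN-CUSTOM", tuple(records))
    return ds, truth


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


def recovery_report(
    truth: ParameterVector,
    draws: PosteriorDraws,
    level: float = 0.90,
    registry=None,
) -> pd.DataFrame:
    """Credible-interval coverage and bias per parameter and derived quantity.

    Derived quantities (compound-level log10 ktrans/w; per-individual log10
    Pinf/w at the reference context) are computed on joint draws, not
    marginals.  Raises on entity mismatch between truth and posterior.
    """
    from skinperm.validation import REFERENCE_CONTEXT, log10_ktrans_w_samples

    lay_t, lay_d = truth.layout, draws.layout
    if (
        lay_t.compounds != lay_d.compounds
        or lay_t.sites != lay_d.sites
        or lay_t.individuals != lay_d.individuals
    ):
        raise ValueError("truth and posterior refer to different entities")
    a = (1.0 - level) / 2.0
    flat = draws.flat()
    rows = []
    for j, name in enumerate(lay_d.names):
        lo, med, hi = np.quantile(flat[:, j], [a, 0.5, 1.0 - a])
        t = truth.values[j]
        rows.append(
            {
                "quantity": name,
                "truth": t,
                "post_median": med,
                "lo": lo,
                "hi": hi,
                "covered": bool(lo <= t <= hi),
                "bias": med - t,
                "width": hi - lo,
            }
        )

    reg = registry if registry is not None else core.default_registry()
    for compound in lay_d.compounds:
        c = reg.compound(compound)
        nom = core.nominal_log10_ktrans(c.MW) + core.nominal_log10_Klipw(c.logKow)
        cmp_part = log10_ktrans_w_samples(draws, compound, reg)
        for ind in lay_d.individuals:
            # the identifiable trans-bilayer quantity is the full per-donor
            # permeability: compound and individual perturbations only enter
            # the data through their sum
            samples = cmp_part + draws.marginal("dlog10_ktrans_ind", ind)
            t = (
                nom
                + truth.values[lay_t.index("dlog10_ktrans_cmp", compound)]
                + truth.values[lay_t.index("dlog10_Klipw_cmp", compound)]
                + truth.values[lay_t.index("dlog10_ktrans_ind", ind)]
            )
            lo, med, hi = np.quantile(samples, [a, 0.5, 1.0 - a])
            rows.append(
                {
                    "quantity": f"log10_ktrans_w[{compound},{ind}]",
                    "truth": t,
                    "post_median": med,
                    "lo": lo,
                    "hi": hi,
                    "covered": bool(lo <= t <= hi),
                    "bias": med - t,
                    "width": hi - lo,
                }
            )

    ref_cmp = lay_d.compounds[0]
    site = REFERENCE_CONTEXT.site if REFERENCE_CONTEXT.site in lay_d.sites else lay_d.sites[0]
    for ind in lay_d.individuals:
        ctx = ExperimentContext(
            compound=ref_cmp,
            site=site,
            preparation=REFERENCE_CONTEXT.preparation,
            vehicle_pH=REFERENCE_CONTEXT.vehicle_pH,
            individual_id=ind,
        )
        samples = np.array(
            [
                np.log10(
                    core.total_permeability(
                        ctx, lay_d.scaling_set(row, ref_cmp, site, ind)
                    ).P_inf_w
                )
                for row in flat[:: max(1, flat.shape[0] // 500)]
            ]
        )
        t = float(
            np.log10(
                core.total_permeability(
                    ctx, truth.scaling_set(ref_cmp, site, ind)
                ).P_inf_w
            )
        )
        lo, med, hi = np.quantile(samples, [a, 0.5, 1.0 - a])
        rows.append(
            {
                "quantity": f"log10_Pinf_w[{ind}]",
                "truth": t,
                "post_median": med,
                "lo": lo,
                "hi": hi,
                "covered": bool(lo <= t <= hi),
                "bias": med - t,
                "width": hi - lo,
            }
        )
    return pd.DataFrame(rows)
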