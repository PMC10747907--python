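"""Unit and property tests of the steady-state permeability model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skinperm import core
from skinperm.core import (
    Compound,
    ExperimentContext,
    ScalingSet,
    apply_scalings,
    compound_nominals,
    default_registry,
    follicular_permeability,
    fraction_nonionized,
    micropore_permeability,
    nominal_log10_Dinf,
    nominal_log10_Kinfw,
    nominal_log10_Klipw,
    nominal_log10_ktrans,
    sc_lipid_pathway_permeability,
    total_permeability,
    viable_tissue_permeability,
)
from conftest import random_scaling_set


def _effective(compound="fentanyl", site="thigh", prep="heat-separated",
               ph=7.40, scalings=ScalingSet(), **overrides):
    reg = default_registry()
    c = reg.compound(compound)
    fixed = reg.fixed_params(prep)
    comp = compound_nominals(c, ph, fixed, reg.qspr)
    eff = apply_scalings(reg.site(site), comp, fixed, scalings, MW=c.MW)
    if overrides:
        from dataclasses import replace

        eff = replace(eff, **overrides)
    return eff, comp.fnon


# ---------------------------------------------------------------------------
# QSPR nominal values (high-precision oracle values frozen from sympy)
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "pKa,pH,expected",
    [
        (8.99, 7.40, 0.02505982123938214),  # ionized base at near-neutral pH
        (8.56, 7.40, 0.06470650095392177),
        (7.00, 7.00, 0.5),  # Henderson-Hasselbalch symmetry
    ],
)
def test_fraction_nonionized_values(pKa, pH, expected):
    assert fraction_nonionized(pKa, pH) == pytest.approx(expected, abs=1e-12)


def test_fraction_nonionized_limits_and_errors():
    assert fraction_nonionized(3.0, 9.0) == pytest.approx(1.0, abs=2e-6)
    with pytest.raises(ValueError):
        fraction_nonionized(float("nan"), 7.0)
    with pytest.raises(ValueError):
        fraction_nonionized(8.99, float("inf"))


@pytest.mark.parametrize(
    "MW,expected",
    [
        (336.5, -6.233756015667486),
        (386.5, -6.494103728898797),
        (1.0, -1.517),  # MW^(1/3) = 1 leaves only the coefficients
    ],
)
def test_nominal_log10_ktrans(MW, expected):
    assert nominal_log10_ktrans(MW) == pytest.approx(expected, abs=1e-12)


def test_nominal_log10_ktrans_rejects_nonpositive():
    with pytest.raises(ValueError):
        nominal_log10_ktrans(0.0)


@pytest.mark.parametrize(
    "logKow,expected",
    [
        (2.86, 1.9500684555795865),
        (3.45, 2.4279684555795865),
        (0.0, math.log10(0.43)),
    ],
)
def test_nominal_log10_Klipw(logKow, expected):
    assert nominal_log10_Klipw(logKow) == pytest.approx(expected, abs=1e-12)


def test_nominal_log10_Kinfw():
    assert nominal_log10_Kinfw(8.99, 7.40) == pytest.approx(
        1.6010220313078231, abs=1e-12
    )
    assert nominal_log10_Kinfw(3.0, 12.0) == pytest.approx(0.0, abs=1e-8)
    assert nominal_log10_Kinfw(7.0, 7.0) == pytest.approx(math.log10(2.0), abs=1e-12)
    # consistency: Kinf/w nominal is exactly 1/fnon
    assert nominal_log10_Kinfw(8.99, 7.40) == pytest.approx(
        -math.log10(fraction_nonionized(8.99, 7.40)), abs=1e-14
    )


def test_nominal_log10_Dinf_monotone_and_degenerate():
    reg = default_registry()
    fx = reg.fixed_params("heat-separated")
    d1 = nominal_log10_Dinf(100.0, fx.ADaq, fx.BDaq)
    d2 = nominal_log10_Dinf(500.0, fx.ADaq, fx.BDaq)
    assert d1 > d2  # aqueous diffusivity decreases with molecular size
    assert nominal_log10_Dinf(100.0, -4.0, 0.0) == nominal_log10_Dinf(500.0, -4.0, 0.0)
    with pytest.raises(ValueError):
        nominal_log10_Dinf(336.5, float("nan"), -0.46)


# ---------------------------------------------------------------------------
# Scaling application
# ---------------------------------------------------------------------------


def test_identity_scalings_reproduce_nominals():
    eff_id, _ = _effective(scalings=ScalingSet())
    eff_cancel, _ = _effective(
        scalings=ScalingSet(hSC_site=1.5, hSC_ind=1.0 / 1.5)
    )
    assert eff_cancel.hSC == pytest.approx(eff_id.hSC, rel=1e-14)
    eff_kt, _ = _effective(
        scalings=ScalingSet(dlog10_ktrans_cmp=0.54, dlog10_ktrans_ind=-0.54)
    )
    assert eff_kt.ktrans == pytest.approx(eff_id.ktrans, rel=1e-12)


def test_out_of_support_scaling_rejected():
    with pytest.raises(ValueError, match="outside prior support"):
        _effective(scalings=ScalingSet(hSC_site=1.6))


def test_compound_registry_holds_study_compounds(registry):
    fen = registry.compound("fentanyl")
    suf = registry.compound("sufentanil")
    assert (fen.MW, fen.pKa, fen.logKow) == (336.5, 8.99, 2.86)
    assert (suf.MW, suf.pKa, suf.logKow) == (386.5, 8.56, 3.45)
    thigh, abd = registry.site("thigh"), registry.site("abdomen")
    assert (thigh.hSC_nom, thigh.Nf_nom, thigh.r1_over_r0) == (29.0, 18.0, 4.59)
    assert (abd.hSC_nom, abd.Nf_nom, abd.r1_over_r0) == (43.4, 21.0, 5.74)


def test_compound_validation():
    with pytest.raises(ValueError):
        Compound("x", MW=-1.0, pKa=7.0, logKow=1.0)
    with pytest.raises(ValueError):
        Compound("x", MW=100.0, pKa=15.0, logKow=1.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.floats(-0.27, 0.27),
    st.floats(-0.27, 0.27),
    st.floats(-0.2, 0.2),
    st.floats(-0.2, 0.2),
)
def test_scaling_composition_homomorphism(a1, a2, b1, b2):
    """Applying composed scalings equals composing applied effects."""
    s1 = ScalingSet(dlog10_ktrans_cmp=a1, dlog10_Klipw_cmp=b1)
    s2 = ScalingSet(dlog10_ktrans_cmp=a2, dlog10_Klipw_cmp=b2)
    composed = s1.compose(s2)
    eff_c, _ = _effective(scalings=composed)
    eff_1, _ = _effective(scalings=s1)
    # the composed additive perturbation acts multiplicatively on ktrans
    assert eff_c.ktrans == pytest.approx(eff_1.ktrans * 10.0**a2, rel=1e-10)
    assert composed.dlog10_ktrans_cmp == pytest.approx(a1 + a2)
    mult = ScalingSet(hSC_site=1.2).compose(ScalingSet(hSC_site=1.1))
    assert mult.hSC_site == pytest.approx(1.32)


# ---------------------------------------------------------------------------
# Pathway components
# ---------------------------------------------------------------------------


def test_follicular_limits_and_linearity():
    eff, fnon = _effective()
    assert follicular_permeability(eff, fnon) > 0
    from dataclasses import replace

    assert follicular_permeability(replace(eff, Nf=0.0), fnon) == 0.0
    assert follicular_permeability(replace(eff, fopen=0.0), fnon) == 0.0
    doubled = follicular_permeability(replace(eff, Nf=2 * eff.Nf), fnon)
    assert doubled == pytest.approx(2.0 * follicular_permeability(eff, fnon), rel=1e-12)
    with pytest.raises(ValueError):
        follicular_permeability(replace(eff, Nf=-1.0), fnon)


def test_micropore_limits():
    from dataclasses import replace

    eff, _ = _effective()
    base = micropore_permeability(eff)
    assert base > 0
    assert micropore_permeability(replace(eff, Np=0.0)) == 0.0
    assert micropore_permeability(replace(eff, Np=3 * eff.Np)) == pytest.approx(
        3.0 * base, rel=1e-12
    )
    # pore radius at/below the solute radius closes the pathway entirely
    assert micropore_permeability(replace(eff, r2=eff.r_solute)) == 0.0
    assert micropore_permeability(replace(eff, r2=eff.r2 / 1e3)) == 0.0


def test_sc_lipid_product_law_and_layer_scaling():
    from dataclasses import replace

    eff, fnon = _effective()
    base = sc_lipid_pathway_permeability(eff, fnon)
    assert sc_lipid_pathway_permeability(eff, 0.0) == 0.0
    half_layers = replace(eff, n_bilayers=eff.n_bilayers / 2.0)
    assert sc_lipid_pathway_permeability(half_layers, fnon) == pytest.approx(
        2.0 * base, rel=1e-12
    )
    root10 = math.sqrt(10.0)
    scaled = replace(eff, ktrans=eff.ktrans * root10, Klipw=eff.Klipw * root10)
    assert sc_lipid_pathway_permeability(scaled, fnon) == pytest.approx(
        10.0 * base, rel=1e-12
    )
    with pytest.raises(ValueError, match="degenerate layer count"):
        sc_lipid_pathway_permeability(replace(eff, hSC=eff.my / 2.0), fnon)


def test_viable_tissue_series_resistance():
    from dataclasses import replace

    eff_hs, _ = _effective(prep="heat-separated")
    eff_dm, _ = _effective(prep="dermatomed")
    assert viable_tissue_permeability(eff_hs) > viable_tissue_permeability(eff_dm)
    assert viable_tissue_permeability(
        replace(eff_hs, hed=0.0, hde=0.0)
    ) == math.inf
    doubled = replace(eff_dm, hed=2 * eff_dm.hed, hde=2 * eff_dm.hde)
    assert viable_tissue_permeability(doubled) == pytest.approx(
        viable_tissue_permeability(eff_dm) / 2.0, rel=1e-12
    )


# ---------------------------------------------------------------------------
# Total permeability: composition, golden regression, invariants
# ---------------------------------------------------------------------------

# identity-scaling predictions, frozen for refactoring protection (cm/s)
GOLDEN_IDENTITY = {
    ("fentanyl", "thigh", "heat-separated", 7.40): 1.296424330317e-07,
    ("fentanyl", "abdomen", "heat-separated", 7.40): 1.213857124436e-07,
    ("fentanyl", "thigh", "dermatomed", 9.37): 5.690298826797e-07,
    ("fentanyl", "thigh", "dermatomed", 2.88): 1.133446175294e-07,
    ("sufentanil", "thigh", "heat-separated", 7.40): 1.757486584866e-07,
    ("sufentanil", "abdomen", "heat-separated", 7.40): 1.500528696098e-07,
    ("sufentanil", "thigh", "dermatomed", 9.37): 1.021082632871e-06,
    ("sufentanil", "thigh", "dermatomed", 2.88): 1.063345972257e-07,
}


@pytest.mark.parametrize("key,expected", sorted(GOLDEN_IDENTITY.items()))
def test_identity_prediction_regression(key, expected):
    compound, site, prep, ph = key
    p = total_permeability(ExperimentContext(compound, site, prep, ph))
    assert p.P_tot_w == pytest.approx(expected, rel=1e-9)


def test_series_composition_without_shunts():
    """With follicle and pore closed, the total is the harmonic (series)
    combination of the SC-lipid and viable-tissue permeabilities."""
    from dataclasses import replace

    eff, fnon = _effective()
    eff0 = replace(eff, Nf=0.0, Np=0.0)
    p = core.pathway_permeabilities(eff0, fnon)
    expected = 1.0 / (1.0 / p.P_sc_lipid + 1.0 / p.P_viable)
    assert p.P_tot_w == pytest.approx(expected, rel=1e-12)
    assert p.P_inf_w == 0.0 and p.P_pore == 0.0


def test_ph_grid_prediction_is_strictly_increasing():
    grid = [2.88, 5.08, 6.02, 6.95, 7.43, 7.95, 8.52, 9.04, 9.37]
    vals = [
        total_permeability(
            ExperimentContext("fentanyl", "thigh", "dermatomed", ph)
        ).P_tot_w
        for ph in grid
    ]
    assert all(b > a for a, b in zip(vals, vals[1:]))


def test_parallel_bounds_on_prior_draws():
    """Each branch bounds the total from below; the branch sum bounds it
    from above, across the prior support."""
    rng = np.random.default_rng(3)
    reg = default_registry()
    for _ in range(1000):
        s = random_scaling_set(rng)
        ctx = ExperimentContext(
            str(rng.choice(["fentanyl", "sufentanil"])),
            str(rng.choice(["thigh", "abdomen"])),
            str(rng.choice(["heat-separated", "dermatomed"])),
            float(rng.uniform(2.5, 10.0)),
        )
        p = total_permeability(ctx, s, registry=reg)
        branch_sum = p.P_inf_w + p.P_sc_lipid + p.P_pore
        assert 0.0 < p.P_tot_w <= branch_sum * (1 + 1e-12)
        assert p.P_tot_w >= p.P_inf_w


def test_ph_monotonicity_across_prior_draws():
    """P_tot/w is non-decreasing in vehicle pH at any fixed parameter draw
    (the solute de-ionizes, opening the lipid route; polar routes carry
    total species)."""
    rng = np.random.default_rng(8)
    grid = np.linspace(2.5, 10.0, 16)
    for _ in range(40):
        s = random_scaling_set(rng)
        compound = str(rng.choice(["fentanyl", "sufentanil"]))
        vals = [
            total_permeability(
                ExperimentContext(compound, "thigh", "dermatomed", float(ph)), s
            ).P_tot_w
            for ph in grid
        ]
        diffs = np.diff(vals)
        assert np.all(diffs >= -1e-18)


def test_unknown_context_rejected():
    with pytest.raises(KeyError):
        total_permeability(
            ExperimentContext("caffeine", "thigh", "heat-separated", 7.4)
        )
    with pytest.raises(KeyError):
        total_permeability(
            ExperimentContext("fentanyl", "forearm", "heat-separated", 7.4)
        )
    with pytest.raises(ValueError):
        ExperimentContext("fentanyl", "thigh", "minced", 7.4)
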