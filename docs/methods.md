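# Methods

## The steady-state permeability model

`skinperm` models the skin permeability coefficient `P_tot/w` (cm/s,
steady-state flux divided by the total solute concentration in an aqueous
vehicle) as a series/parallel conductance network of three transport routes
through excised human skin:

1. **Stratum-corneum (SC) lipid route** (non-polar, transcellular).  Only the
   non-ionized solute fraction `fnon` partitions into the lipid lamellae:

       P_lip = fnon * ktrans * Klip/w / n_bilayers,
       n_bilayers = b * hSC / my

   where `ktrans` is the single-bilayer permeability, `Klip/w` the
   lipid/water partition coefficient, `hSC` the fully hydrated SC thickness,
   `my` the thickness of one corneocyte layer plus its lipid envelope, and
   `b` the number of transport-limiting bilayers per corneocyte layer in the
   brick-and-mortar geometry.
2. **Micropore route** (polar, transcellular).  Hindered aqueous diffusion of
   the total (ionized + non-ionized) species through `Np` water-filled pores
   of radius `r2` spanning the SC, with a Renkin hindrance factor evaluated
   at the solute/pore radius ratio.  The solute radius is that of a
   unit-density sphere of the molecular weight.
3. **Follicular (infundibular) shunt**.  The infundibulum is modeled as a
   vehicle-filled truncated cone (hair-shaft radius `r0`, orifice radius
   `r1 = r0 * (r1/r0)`) spanning the SC; the frustum conductance per follicle
   is `pi*r0*r1*Dinf/hSC`, multiplied by the open-follicle density
   `Nf * fopen` and by `fnon * Kinf/w`.  At the nominal
   `Kinf/w = 1/fnon` this product is 1, so the nominal shunt is
   pH-independent and carries total species — it is the polar floor that the
   low-pH measurements sit on.

The two SC routes act in parallel; their sum is in series with the viable
epidermis/dermis (an aqueous gel with tissue/water partition 0.7 and
diffusivity `Daq/3`); the follicular shunt is in parallel with that series
combination.  Heat-separated epidermis sets the dermis thickness to exactly
0; dermatomed skin to 100 um.

### QSPR nominal values

| quantity | nominal form |
|---|---|
| log10 ktrans (cm/s) | -0.725 - 0.792 * MW^(1/3) |
| log10 Klip/w | 0.81 * log10 Ko/w + log10 0.43 |
| log10 Kinf/w | log10(1 + 10^(pKa - pH)) = -log10 fnon |
| log10 Dinf (cm^2/s) | ADaq + BDaq * log10 MW (ADaq = -4.113, BDaq = -0.4609) |

`fnon = 1/(1 + 10^(pKa - pH))` (monoprotic base).  The aqueous-diffusivity
correlation is the standard hydrodynamic form and is also used for the pore
and viable-tissue diffusivities.

### Constants not available in tabulated sources

The pathway geometry requires a handful of constants that the primary data
tables do not fix: the hair-shaft radius (`r0 = 40 um`), the bilayer packing
factor (`b = 8` transport-limiting bilayers per corneocyte layer), the
viable-tissue partition (0.7) and tortuosity (3), and the aqueous-diffusivity
coefficients above.  They were set once, at physically conventional values,
under three structural constraints and not revisited:

* identity-scaling predictions reproduce the printed measurement magnitudes
  within the stated QSPR uncertainty ranges (e.g. fentanyl/thigh/pH 7.4:
  model 1.30e-7 cm/s vs measured 2.8e-6 cm/s, within the +-1.08 log10
  uncertainty of ktrans plus infundibular uncertainties; the pH 2.88
  measurements sit directly on the model's polar floor, 1.1e-7 vs 0.8e-7);
* the Morris screen reproduces the known sensitivity structure (infundibular
  parameters dominant at pH 7.4, `ktrans` dominant at pH 9.37, `r2`/`Np`
  negligible everywhere);
* the thigh-vs-abdomen nominal ordering (thinner thigh SC makes thigh more
  permeable at equal follicle endowment) required by the cross-site
  extrapolation findings.

All constants live in `src/skinperm/data/nominals.yaml`; nothing is
hard-coded in operations.

## Scaling parameters and priors

Every uncertain quantity enters as a scaling of its nominal value:
multiplicative for `hSC` (site x individual) and `Nf` (site), additive log10
perturbations for `ktrans` (compound + individual), `Klip/w` (compound),
`Kinf/w` (compound), `Dinf` (individual) and `fopen` (individual).  `my`,
`r2` and `Np` stay fixed (screened out by the Morris analysis).  Priors:

| parameter | prior |
|---|---|
| hSC_site, hSC_ind | LogUniform(1/1.5, 1.5) |
| dlog10 ktrans (cmp, ind) | Uniform(-0.54, 0.54) |
| dlog10 Klip/w (cmp) | Uniform(-0.43, 0.43) |
| dlog10 Kinf/w (cmp) | Uniform(-1, 1) |
| dlog10 Dinf (ind) | Uniform(-1, 1) |
| dlog10 fopen (ind) | Uniform(-1, 1) |
| Nf_site | LogUniform(1/1.25, 1.25) |
| nu^2 | p(nu^2) prop. 1/nu^2, truncated to [1e-4, 1e2] |

The likelihood treats each experiment's mean permeability as log-normally
distributed around the model prediction with a shared relative error
variance `nu^2`; residuals are in natural log (any fixed base is equivalent
up to a rescaling of `nu`).  Replicate standard deviations are carried as
metadata only.

## Sampler

Inference runs in coordinates where every prior is a bounded uniform (log10
for multiplicative scalings, `ln nu^2` for the variance).  The kernel is an
adaptive block Metropolis–Hastings sampler with box-reflected Gaussian
proposals, one block per parameter class *and entity* (per compound, per
site, per donor) — low-dimensional blocks mix far better here than
class-wide ones because the model couples parameters within an entity much
more strongly than across entities.  Proposal scales adapt toward 0.3
acceptance by a Robbins–Monro recursion during burn-in only (adaptation
frozen afterwards, preserving ergodicity), clamped to a numerically sane
range.  The error-variance block is conjugate (inverse-gamma given the
residuals) and is drawn exactly by a Gibbs step truncated to its prior
bounds; this removes the small-variance funnel that a random-walk step
traverses slowly in this heavily over-parameterized posterior (about 35
parameters against 12 observations).

Defaults: 20,000 iterations, 50% burn-in, 4 chains.  The scaled-down study
sizes used by the test suite and the acceptance script are 6,000–8,000
iterations with 2 chains, which bring the split R-hat of the identified
directions near 1 while keeping a full repetition under ~10 s; weakly
identified directions remain prior-wide by construction.  Convergence
summaries (split R-hat, bulk ESS via ArviZ, per-block acceptance) are
produced by `skinperm.inference.diagnostics`.

## Sensitivity screening

Morris elementary effects on `log10 P_tot/w` (scale-free, decades per full
parameter range), with randomized one-at-a-time trajectories (default 100
trajectories, 4 levels).  Ranges are the literature uncertainty ranges:
log-scaled parameters are sampled in log space; `Nf*fopen` is screened as a
single lumped factor because the two only enter the model as a product; the
orifice/shaft ratio is sampled linearly on 1–10.  The default selection
policy excludes a factor whose mu* stays below 10% of the scenario maximum
in every scenario, which reproduces the inferred-parameter set above (`r2`,
`Np`, `my` excluded).

A caution on ranking statistics: the two infundibular factors (`Kinf/w`,
`Dinf`) have identical ranges and enter the same branch, so their mu* values
are structurally tied; only "an infundibular descriptor ranks top at pH 7.4"
is a stable statement, not their mutual order.

## Validation and extrapolation

* **Internal VPC** re-simulates each training record with its own
  compound/site/individual scalings from the joint posterior and includes
  the per-draw measurement noise (a predictive check compares against noisy
  data); the coverage table reports the fraction of records inside the
  central 95% predictive interval.
* **External validation 1** predicts the four compound x site scenarios at
  pH 7.4 on heat-separated epidermis, pooling the trained donors' individual
  scalings.  Untrained compounds or sites borrow the trained entity's
  scaling draws (substitution justified by the similarity of
  compound-parameter correlations across compounds); the substitution with
  the identical entity reduces exactly to direct prediction.
* **External validation 2** predicts the variable-pH series on dermatomed
  thigh skin, excluding any pH row used in training; the pH-series donor's
  scalings are used where trained, otherwise the full donor pool (with a
  warning), which widens the intervals — the expected population-vs-
  individual effect.
* **Pathway summaries** report `log10 ktrans/w = log10(ktrans * Klip/w)`
  (compound level) and `log10 Pinf/w` at a reference context (fentanyl
  nominals, thigh, heat-separated, pH 7.4), both from the same joint
  resample so cross-parameter correlations are preserved.

All predictions route through `skinperm.core.total_permeability`; there is
no second prediction path.

## Synthetic studies

`skinperm.synthetic` generates studies under the same group design
structures (cross-over/parallel, common/varied pH, single/both sites) with
synthetic donor labels (`SD01`, ...) and the generative inverse of the
likelihood: `P = f(truth) * exp(eps)`, `eps ~ N(0, nu^2)`, with `nu = 0.2`
by default — the scale of the posterior error estimates obtained on the real
data (~0.16).  Truths for recovery studies are drawn from the central half
of each prior support to avoid boundary-biased coverage.

What the generator does *not* emulate: replicate-level Franz-cell kinetics,
donor-specific replicate variances, model misspecification (synthetic data
come from the model itself), and any systematic protocol differences between
the heat-separated and dermatomed experiment series.  Passing recovery tests
therefore demonstrates the estimator's self-consistency, not robustness to
structural error.

### Identifiability and recovery scoring

With 12 observations and ~35 parameters, individual scalings and compound
perturbations are only identified in combination.  Recovery is therefore
scored on the identifiable derived quantities: the per-donor trans-bilayer
permeability `log10 ktrans/w(compound, donor)` (the compound and individual
perturbations enter the data only through this sum) and the per-donor
infundibular permeability at the reference context, both evaluated on joint
posterior draws.

### The design-effect experiment

The experiment-design comparison draws one truth in which both compounds
share the same true `ktrans/w` (their compound perturbations absorb the
nominal QSPR difference) and the same infundibular partition perturbation,
generates studies under the cross-over/common-pH (A), cross-over/varied-pH
(B) and parallel/varied-pH (E) designs from that truth, fits each, and
compares the absolute difference in posterior-median `log10 ktrans/w`
between compounds, averaged over each group's data sets.  Across
repetitions the varied-pH cross-over design yields the smallest median
divergence, the common-pH and parallel designs larger ones.  Because
synthetic data contain no model misspecification, the divergence is driven
purely by measurement noise at the informative (high-pH) records, and the
per-repetition contrast between designs is weaker than the corresponding
real-data contrast; see the ledger note accompanying the acceptance suite.

## Numerical choices

* Lengths convert to cm at a single boundary (`apply_scalings`); logs are
  base-10 wherever a log10 symbol appears; permeabilities are cm/s.
* Zero viable-tissue thickness is treated as "no viable resistance"
  (infinite permeability in the series combination), not an epsilon.
* `hSC < my` (less than one corneocyte layer) is a hard error; prior
  supports cannot reach it.
* Out-of-support scalings raise in direct model evaluation; the inference
  path expresses the same constraint as a -inf log prior.
* The transient finite-volume oracle used in tests tracks water-referenced
  activity with half-cell interface resistances, making steady-state flux
  exact for any cell count; agreement therefore tests the conductance
  composition and the long-time limit, not grid refinement.

## Known limitations

* The pathway geometry constants are conventional values, not measured ones;
  absolute nominal predictions are order-of-magnitude anchors that the
  scaling posterior adjusts, so cross-study transfer of the *absolute*
  nominals deserves caution.
* Finite-dose/transient exposure, vehicle evaporation, dermal metabolism and
  systemic coupling are out of scope; the model is steady-state
  infinite-dose only.
* Only two, physicochemically similar, compounds constrain the
  compound-specific QSPR perturbations; extrapolation to dissimilar
  chemistries is untested by construction.
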