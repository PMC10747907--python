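# skinperm

Mechanistic modeling of the human skin permeability coefficient with
Bayesian calibration and experiment-design analysis.

## The problem

In-vitro permeation tests measure the steady-state permeability coefficient
`P_tot/w` (cm/s) of a compound across excised skin, but a single experiment
only speaks for one donor, one anatomical site, one vehicle.  `skinperm`
implements a physiologically based, pathway-resolved model of `P_tot/w` and
a Bayesian workflow that learns compound-, site- and individual-specific
parameter distributions from small permeability data sets, then extrapolates
to untested compounds, sites and vehicle pH levels — and quantifies how the
*design* of the training experiments (cross-over vs parallel, single vs
varied pH, single vs both sites) governs what the model can learn.

It is aimed at dermal PBPK modelers and IVPT experimentalists deciding how
to allocate scarce donor skin.

## The model

`P_tot/w` is a conductance network of three routes:

* SC lipid route: `P_lip = fnon * ktrans * Klip/w / n_bilayers` — carries
  the non-ionized fraction `fnon = 1/(1 + 10^(pKa - pH))`;
* micropore route: hindered aqueous diffusion of total species through
  `Np` pores of radius `r2` across the SC;
* follicular shunt: a vehicle-filled infundibular cone of conductance
  `Nf * fopen * pi * r0 * r1 * Kinf/w * Dinf / hSC`, pH-independent at its
  nominal parameterization;

with the SC routes in series with the viable epidermis/dermis and the shunt
in parallel.  Nominal values come from QSPR correlations
(`log10 ktrans = -0.725 - 0.792 MW^(1/3)`,
`log10 Klip/w = 0.81 log10 Ko/w + log10 0.43`, ...) and published skin
morphometry; every uncertain quantity is a scaling of its nominal, inferred
by an adaptive block Metropolis–Hastings sampler under the posterior

    p(theta, nu | d)  prop.  prod_i N(log d_i | log f_i(theta), nu^2)
                             * p(theta) * 1/nu^2 .

See `docs/methods.md` for the full model, priors and numerical choices.

## Worked example

Fit the model to a cross-over/varied-pH training data set built from the
packaged fentanyl/sufentanil measurements, then check it against the
observed pH 7.4 ranges:

```bash
skinperm datasets --group B --seed 7 --out work/
skinperm fit --dataset work/B1.csv --group B --iterations 8000 --chains 2 \
             --seed 42 --out work/chains
skinperm validate --chains work/chains --dataset work/B1.csv --group B \
                  --mode external1 --out work/val
```

which prints (permeabilities in cm/s):

```
dataset   compound    site  pred_median      pred_lo  pred_hi      obs_min  obs_median  obs_max
     B1   fentanyl abdomen     0.000004 5.421398e-07 0.000011 1.530000e-06    0.000004 0.000004
     B1   fentanyl   thigh     0.000004 8.148896e-07 0.000009 8.300000e-07    0.000003 0.000005
     B1 sufentanil abdomen     0.000005 7.435638e-07 0.000013 2.330000e-06    0.000004 0.000005
     B1 sufentanil   thigh     0.000005 1.171362e-06 0.000011 1.530000e-06    0.000004 0.000006
```

Every posterior-median prediction falls inside the observed range for its
compound/site pair — the expected behaviour for a cross-over design trained
at two pH levels.  A single forward evaluation is also available:

```bash
skinperm simulate --compound fentanyl --site thigh --ph 7.4
```

```
pathway      permeability_cm_s
P_tot/w      1.296424e-07
k_trans/w    5.203702e-05
P_sc_lipid   1.630048e-08
P_inf/w      1.133342e-07
P_pore       9.937230e-12
P_viable     1.231089e-04
```

At pH 7.4 the follicular shunt (`P_inf/w`) dominates the nominal
prediction — fentanyl is ~97.5% ionized there, closing the lipid route;
the micropore route is negligible throughout.

Other entry points: `skinperm sensitivity` (Morris screen),
`skinperm synth` (synthetic studies with known truth), and the library
modules `skinperm.core`, `skinperm.datasets`, `skinperm.sensitivity`,
`skinperm.inference`, `skinperm.validation`, `skinperm.synthetic`.

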