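# Versioned nominal-parameter and constants registry for the skin permeation
# model. All lengths in the units stated; conversion to cm happens at one
# boundary inside skinperm.core.apply_scalings.
#
# Sources: compound descriptors and QSPR coefficients from published
# fentanyl/sufentanil physicochemical data and stratum-corneum QSPR
# correlations; site geometry (SC thickness, follicle density, orifice/shaft
# radius ratio) from published skin morphometry; micropore descriptors from
# the porous-pathway extension of the brick-and-mortar SC model. Constants not
# available in tabulated form (hair shaft radius, bilayer packing, viable
# tissue properties, aqueous-diffusivity coefficients) are fixed here at
# literature-scale values and documented in docs/methods.md.

compounds:
  fentanyl:
    MW: 336.5          # g/mol
    pKa: 8.99          # basic, monoprotic
    logKow: 2.86
  sufentanil:
    MW: 386.5
    pKa: 8.56
    logKow: 3.45

sites:
  thigh:
    hSC_nom_um: 29.0       # stratum corneum thickness, fully hydrated
    Nf_nom_per_cm2: 18.0   # follicle density
    r1_over_r0: 4.59       # follicle orifice radius / hair shaft radius
  abdomen:
    hSC_nom_um: 43.4
    Nf_nom_per_cm2: 21.0
    r1_over_r0: 5.74

fixed:
  hed_um: 100.0            # viable epidermis thickness
  hde_um:                  # dermis thickness by skin preparation
    heat-separated: 0.0
    dermatomed: 100.0
  my_um: 2.9               # lipid bilayer envelope + corneocyte thickness
  fopen_nom: 0.015         # proportion of open follicles
  r0_um: 40.0              # hair shaft radius
  r2_nm: 1.6               # micropore radius
  Np_per_cm2: 373000.0     # micropore density
  # log10 Daq (cm^2/s) = ADaq + BDaq * log10(MW): hydrodynamic aqueous
  # diffusivity correlation; also used for the infundibular diffusivity
  # nominal.
  ADaq: -4.113
  BDaq: -0.4609
  # Transport-limiting lipid bilayers per corneocyte layer in the
  # brick-and-mortar SC geometry (total count = this * hSC / my).
  bilayers_per_cc_layer: 8.0
  # Viable epidermis/dermis treated as an aqueous gel.
  K_viable_w: 0.7          # tissue/water partition coefficient
  viable_tortuosity: 3.0   # Daq reduction factor in viable tissue
  solute_density_g_cm3: 1.0  # for the hydrodynamic solute radius

qspr:
  # log10 ktrans (cm/s) = intercept + slope * MW^(1/3)
  ktrans:
    intercept: -0.725
    slope: -0.792
  # log10 Klip/w = slope * log10 Ko/w + log10(intercept_factor)
  klipw:
    slope: 0.81
    intercept_factor: 0.43
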