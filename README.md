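# mepflux

Tools for estimating the flux through the plastidial MEP isoprenoid pathway
from ¹³CO₂ → isoprene labeling time courses, analysing HDR
((E)-4-hydroxy-3-methylbut-2-enyl diphosphate reductase) enzyme assays, and
doing DMADP/IDP precursor-demand stoichiometry for terpenoid product
profiles.

## What is in the box

| Module | Purpose |
| --- | --- |
| `mepflux.label_model` | Closed-form fractional-labeling curve of the four-pool chain (DXP → MEcDP → HMBDP → IDP+DMADP) plus an independent adaptive-ODE oracle. `f(t)/m` is the CDF of a hypoexponential distribution. |
| `mepflux.pool_estimation` | Plastidial pool sizes from total pools and final labeling fractions, referenced to isoprene. |
| `mepflux.flux_fit` | Least-squares estimation of the pathway flux J (optionally co-fitting the plateau m), with multi-start initialization and a residual-resampling bootstrap. |
| `mepflux.enzyme_kinetics` | Progress-curve fits `y = a(1−exp(−bt))` → initial velocity `v0 = a·b`; Michaelis–Menten constants via nonlinear least squares or Lineweaver–Burk; kcat, catalytic efficiency, DMADP:IDP product ratios. |
| `mepflux.precursor_demand` | Unit demands (1 DMADP, n−1 IDP per C5n prenyl diphosphate), profile aggregation, and limiting-reagent supply-vs-demand balance. |
| `mepflux.synthetic_data` | Seeded generators for labeling curves, assay tables and pool tables so every stage is testable offline. |
| `mepflux.io` / `mepflux.cli` | Strict CSV readers/writers and the `mepflux` command-line tool. |

Units package-wide: pools in nmol·gFW⁻¹, time in minutes, flux in
nmol·gFW⁻¹·min⁻¹, concentrations in µM.

## CLI

```sh
# write seeded synthetic fixtures (labeling.csv, assay.csv, pools.csv, ...)
mepflux simulate all --out fixtures/ --seed 1

# fit the pathway flux from a time course + pool table
mepflux fit-flux --timecourse fixtures/labeling.csv --pools fixtures/pools.csv \
    --out flux.json [--fit-m] [--boot 500 --seed 1]

# enzyme kinetics from an assay table
mepflux fit-kinetics --assay fixtures/assay.csv --enzyme-molar-uM 0.5 \
    --method nls --out kinetics.json

# plastidial pools
mepflux pools --pools fixtures/pools.csv --out pools.json

# precursor demand and supply balance
mepflux demand --profile fixtures/profile.csv --supply-ratio 1:6
```

CSV schemas: time courses `time_min,fraction[,sd]`; pool tables
`metabolite,total_pool_nmol_per_gfw,final_fraction` (an `isoprene` row
supplies the reference plateau); assays
`substrate_uM,time_min,product_uM[,dmadp_uM,idp_uM]`; profiles `class,moles`.

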