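# auroraloop

Two-state conformational-equilibrium analysis of single-molecule fluorescence
traces, built around the quench-reporter assay for the activation loop of
Aurora-A kinase.

Protein kinases are switched on and off by the orientation of their
activation loop, and most inhibitors bind one loop conformation more tightly
than the other.  In the assay this package models, two dye labels on the
kinase domain quench each other when the loop is inactive and fluoresce when
it is active, so each tethered molecule produces a telegraph-like intensity
trace as the loop interconverts.  From ensembles of such traces one can read
off the conformational equilibrium constant `K_eq = [inactive]/[active]`, the
switching rate constants, the free-energy shifts caused by phosphorylation
and by ligands, and — through a conformational-selection binding model — what
a ligand's conformation-specific affinities imply for the dissociation
constant measured in a bulk assay:

    ΔG = −RT ln K_eq
    ΔΔG_ligand = ΔG_apo − ΔG_ligand
    K_d,overall = (1 + K_eq,free) / (1/K_d,active + K_eq,free/K_d,inactive)

The package is organized as a library (`src/auroraloop/`) driven by numbered
analysis scripts (`analysis/`):

| module | what it does |
|---|---|
| `simulate` | telegraph-process trace generator with exact frame integration and log-normal emission |
| `histogram` | pooled intensity histograms; two-log-normal fits (binned LSQ and raw-intensity MLE); populations |
| `dwell` | density-crossing threshold, dwell extraction with censoring, single-exponential rate fits |
| `thermo` | K_eq, ΔG, ΔΔG thermodynamic cycle, phosphorylation-independence check |
| `binding` | ligand discrimination, required discrimination, the K_d,overall surface, contour/equidistant/plateau geometry |
| `fret` | Förster efficiencies and quench-band classification for reporter design |
| `pipeline` | YAML-configured end-to-end runs and report tables |
| `datasets` | published reference occupancies and rates used as inputs |

A thin CLI (`auroraloop simulate|histfit|dwell|thermo|discriminate|surface|fret|report`)
wraps the same functions.

## Worked example

Simulate the unphosphorylated kinase regime, recover its populations and
kinetics, and convert to thermodynamics:

```python
from auroraloop import (
    SimulationConfig, TwoStateRates, simulate_ensemble,
    populations_from_fit, equilibrium_constant, free_energy,
)
from auroraloop.histogram import fit_two_lognormals_mle, pool_intensities

cfg = SimulationConfig(rates=TwoStateRates(k_active=2.1, k_inactive=2.4),
                       n_molecules=500, seed=101)
ens = simulate_ensemble(cfg)                       # 500 molecules x 500 frames, 80 ms
fit = fit_two_lognormals_mle(pool_intensities(ens.traces))
pops = populations_from_fit(fit, "inactive_low")
keq, keq_err = equilibrium_constant(pops)
dg, dg_err = free_energy(keq, keq_err)
print(f"inactive {pops.pct_inactive:.1f}%  K_eq {keq:.2f}  dG {dg:+.2f} kcal/mol")
```

prints

```
inactive 51.0%  K_eq 1.04  dG -0.02 kcal/mol
```

i.e. the pipeline recovers the configured stationary population (53.3%
inactive, `K_eq` = 2.4/2.1 ≈ 1.14, ΔG ≈ −0.08 kcal/mol) to within the
documented transition-frame bias of a couple of percentage points (see
`docs/methods.md`).  Running the numbered drivers end to end:

```sh
python analysis/01_fret_reporter_design.py   # 87% / 100% FRET; quench band classification
python analysis/02_simulate_ensembles.py     # both kinetic regimes -> results/traces_*.csv
python analysis/03_fit_histograms.py         # populations: 51.0% / 22.4% inactive (MLE)
python analysis/04_dwell_kinetics.py         # k_active 1.87 / 2.19 s^-1 (true 2.1 / 2.3)
python analysis/05_thermodynamics.py         # K_eq, dG table; independence max dev 0.17 kcal/mol
python analysis/06_ligand_discrimination.py  # 331/64/30-fold etc. required discrimination
python analysis/07_binding_surface.py        # K_d,overall surfaces, plateaus, equidistant lines
```

Each script states what it found on stdout and writes its tables (CSV/JSON,
plus two PNG contour plots) under `results/`.

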