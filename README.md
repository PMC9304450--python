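# ataa

Aortic biomarker toolkit for small-animal aneurysm studies: fits a
Holzapfel–Gasser–Ogden (HGO) arterial-wall model to biaxial myograph data,
computes geometric and hemodynamic biomarkers (tortuosity index, maximum
diameter, TAWSS, OSI, peak Reynolds and Womersley numbers, three-element
Windkessel pressures), and relates biomarkers to right-censored lifespan
through a Tobit regression with pseudo-r² correlation maps. Synthetic-data
generators with ground-truth sidecars stand in for MRI segmentation and 3D
fluid–structure solvers, so every pipeline stage is testable offline.

## Layout

| module | contents |
| --- | --- |
| `ataa.constitutive` | HGO strain energy, analytic biaxial Cauchy stresses, multistart parameter fitting, `E = c(1+ν)`, thin-wall (Laplace) helpers |
| `ataa.hemodynamics` | Carreau–Yasuda viscosity, RCR Windkessel ODE (implicit trapezoid), Robin wall traction, TAWSS/OSI, field summaries, Re/Wo |
| `ataa.geometry` | centerlines, arc/chord lengths, tortuosity index, max diameter, mask-stack extraction |
| `ataa.stats` | right-censored Gaussian (Tobit) MLE, pseudo-r² (two conventions), correlation maps, Δ-biomarkers |
| `ataa.synthetic` | seeded generators: biaxial protocols, WSS fields, tortuous vessels (+ voxelization), inflow waveforms, censored cohorts |
| `ataa.pipeline` / `ataa.cli` | per-subject biomarker assembly, correlation runs, sensitivity harness, `ataa` command-line verbs |
| `ataa.datasets` | bundled ten-subject reference cohort, outlet RCR parameters, observed biomarker ranges |

## CLI

```bash
ataa simulate --kind cohort --seed 1 --out work/      # synthetic inputs
ataa simulate --kind inflow --out work/
ataa fit-hgo --data work/biaxial.csv --out work/fit.json
ataa windkessel --waveform work/inflow.csv --windkessel work/windkessel.json --out work/p.csv
ataa biomarkers --subjects subjects.json --waveform work/inflow.csv \
    --windkessel work/windkessel.json --out work/biomarkers.csv
ataa tobit-map --cohort work/cohort_6mo.csv --censor 25 --out work/maps/
ataa sensitivity --params fit_params.json --waveform work/inflow.csv \
    --windkessel work/windkessel.json --out work/sensitivity.csv
ataa report --biomarkers work/biomarkers.csv --map work/maps/correlation_map.csv --out report.html
```

All CSV outputs carry a `#`-prefixed provenance header (tool version, seed,
config hash); generators write ground truth to `<output>.truth.json`
sidecars.

## Notes on conventions

- The fiber term uses the standard HGO form `k1/(2 k2) Σ (exp(k2 E²) − 1)`
  with a tension-only switch (configurable), and incompressibility
  eliminates the radial stretch before differentiation.
- The Carreau–Yasuda law uses the standard plus-sign form
  `η∞ + (η0−η∞)(1+(λγ̇)^a)^((n−1)/a)`.
- `pseudo_r2` offers two conventions: `mckelvey_zavoina` (explained latent
  variance over itself plus `Nσ²`) and `squared_correlation` (observed vs
  fitted). Both reduce exactly to the OLS r² on uncensored data; the
  bundled reference-cohort value of 0.21 for tortuosity vs lifespan is
  reproduced by the squared-correlation convention.
- OSI is defined as 0 at nodes with identically zero wall shear.
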