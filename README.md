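# azmech

Analysis pipeline for the mechanical unfolding of azurin — a 128-residue
β-barrel cupredoxin with a type-I copper centre — with and without its
copper cofactor. In single-molecule force spectroscopy, a heptameric azurin
polyprotein pulled at constant velocity produces a sawtooth of rupture
peaks; each domain unfolds through a 2-state pathway (native → unfolded) or
through one or two partially unfolded intermediates (3- and 4-state
pathways), and copper binding reshapes that pathway mixture by sequestering
the chain segment held inside its coordination sphere (His46, Cys112,
His117 equatorial; Gly45, Met121 axial).

The package is aimed at single-molecule biophysicists who want a tested,
end-to-end reimplementation of this analysis that runs entirely on synthetic
data:

* **`azmech.synthetic`** — generators for sawtooth force-extension traces
  (kinetic Monte Carlo over Bell-Evans barriers, worm-like chain + cantilever
  mechanics), multi-exponential fluorescence decays convolved with an
  instrument response, and bead-per-residue β-barrel structures with an
  optional 5-ligand copper site.
* **`azmech.wlc`** — rupture-peak detection and flank fitting with the WLC
  interpolation formula F(x) = (kBT/p)[¼(1−x/Lc)⁻² − ¼ + x/Lc].
* **`azmech.pathways`** — grouping of rupture events into per-domain
  cascades, 2/3/4-state classification, flux percentages with trace-level
  bootstrap errors, force correlations, permutation tests, speed sweeps.
* **`azmech.contour`** — expected contour-length arithmetic:
  ΔLc = (n − sequestered)·0.36 nm/aa − folded end-to-end (for azurin,
  (128−23)·0.36 − 1.4 = 36.4 nm).
* **`azmech.pulling`** — a coarse-grained (Gō-type) constant-velocity
  pulling simulator with the copper coordination sphere as harmonic springs
  of tunable stiffness, an equatorial-only variant, and controlled deletion
  of the constraints at prescribed extensions.
* **`azmech.trajectory`** — β-strand geometric-centre separations, rupture
  order, residue-pair distances and peak statistics on simulated pulls.
* **`azmech.tcspc`** — fluorescence lifetime fitting by iterative
  reconvolution (Grinvald-Steinberg recursion, Marquardt least squares,
  fractional-channel shift), reporting τ_m = Σ αᵢτᵢ.

The numbered scripts under `analysis/` run the full study on synthetic data
and write tables under `results/`; `docs/methods.md` documents the models,
parameter choices and limitations.

## Worked example

```python
import numpy as np
from azmech import (GeneratorConfig, apo_pathways, generate_dataset,
                    classify_dataset, bootstrap_flux)

cfg = GeneratorConfig(seed=0, noise_sd=5.0)          # 7 domains, 400 nm/s
traces = generate_dataset(cfg, apo_pathways(), 200, seed=123)
records = classify_dataset(traces)
est = bootstrap_flux(records, n_resamples=500, seed=1)
print({k: round(v, 1) for k, v in est.fraction.items()},
      "+/-", round(est.se[3], 1))
```

prints

```
{2: 46.7, 3: 53.2, 4: 0.1} +/- 1.4
```

i.e. 53.2 ± 1.4% of the classified domains unfolded through an
intermediate, against a generated truth of 54.8% for this 200-trace sample
— the residual deficit being domains whose intermediate ruptured within one
sampling interval of the native event, which no detector can resolve. The
fitted contour-length increments recover the generated 7.5 nm
(native → intermediate) and 37.2 nm (total) medians to within 0.2 nm.

Running `analysis/05_pull_barrel.py` pulls the packaged barrel fixture and
prints the copper imprint on the simulated traces:

```
curtailment extension medians (nm):
apo             11.96
full_k25         9.18
no_axial_k25    10.11
```

— the full coordination sphere curtails chain release ~2.8 nm before the
bare construct, and constraining only the equatorial bonds lands in
between: releasing the axial ligands (Gly45, Met121) frees exactly the
extra chain segment they pin down.

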