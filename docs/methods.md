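# Methods

`azmech` reimplements, as a tested pipeline on synthetic data, the analysis
chain used to study the mechanical unfolding of azurin with and without its
copper cofactor: single-molecule force-extension (FX) analysis of polyprotein
pulling, unfolding-pathway classification, structure-based contour-length
accounting, a coarse-grained pulling simulator carrying a harmonic model of
the type-I copper coordination sphere, and time-correlated single-photon
counting (TCSPC) lifetime fitting. Units are nm, pN, ns and K throughout the
analysis layer; kB·T at 298 K is fixed to 4.114 pN·nm. The simulator works
internally in angstrom and kcal/mol and converts at its boundary
(1 kcal·mol⁻¹·Å⁻¹ = 69.48 pN).

## Synthetic force-extension traces

A trace is a constant-velocity pull of a heptameric polyprotein recorded as
force versus tip-sample extension. At each sample the molecular extension x
solves the series balance between the worm-like chain (WLC)

    F(x) = (kB T / p) [ 1/4 (1 - x/Lc)^-2 - 1/4 + x/Lc ]

at the current total contour length Lc and the cantilever load line
k_c (z - x), with the base position z advancing at the pulling speed. Each
folded domain draws a pathway from a weighted mixture — 2-state (one rupture
releasing the full ~37 nm), 3-state (a native rupture releasing the
native-to-intermediate step, then the intermediate's rupture), or 4-state
(two intermediates) — and every pending barrier ruptures stochastically with
the Bell-Evans rate k(F) = k0 exp(F Δx‡ / kB T), sampled per time step
(kinetic Monte Carlo). A rupture adds its state's ΔLc to the chain; a final
detachment barrier (releasing nothing) ends the trace. Gaussian noise is
added to the force channel only; extension is the noise-free solution of the
force balance, which is what makes the single-sample extension jump at a
rupture (≈ force drop / k_c) a clean detector feature (see below).

Default conditions mirror the experimental setup: 7 domains, 400 nm/s,
k_c = 40 pN/nm, 5 kHz sampling, 5 pN force noise, p = 0.4 nm, T = 298 K.
Default mixtures: apo 44/56% (2-/3-state) with ΔLc totals 37.2 nm and a
7.5 nm native-to-intermediate step; copper-bound 23/61/16% (2-/3-/4-state)
with 37.0 nm total, a 6.7 nm first step and a 5.3 nm second step.

Two kinetic choices matter and were set deliberately:

* **Static disorder.** Each domain carries one normally distributed strength
  offset (SD 9 pN) that shifts the rupture forces of *all* of its states
  together; the Bell width is kept narrow (Δx‡ = 2.0 nm, kB T/Δx‡ ≈ 2 pN).
  Most of the ~10 pN width of the rupture-force histograms therefore comes
  from molecule-to-molecule variation, which (i) reproduces the observed
  within-molecule correlation between native and intermediate rupture forces
  and (ii) keeps the intermediate's threshold below its own native's rupture
  force, so the intermediate reloads measurably instead of rupturing within
  the dead time. With a wide Bell width instead, a large fraction of
  intermediates ruptures within a few samples of the native event and no
  detector can resolve them.
* **Rate prefactors** (k0 ≈ 2.5e-10 s⁻¹ native, 1e-8 s⁻¹ intermediate for
  the apo form; scaled down ~30× for the stronger copper-bound states) place
  the mean peak forces at ≈56/50 pN (apo native/intermediate) and
  ≈64/56/53 pN (holo), inside the experimentally reported 45-65 pN band at
  400 nm/s. Mean rupture force grows logarithmically with pulling speed, as
  the Bell model requires.

The generator does **not** emulate: cantilever thermal dynamics or drift,
extension-channel noise, surface adhesion artifacts, misfolded or skipped
domains, or detector-resolution loss at low pulling speeds. Recovery results
on these traces therefore demonstrate the correctness of the analysis chain
under the stated statistical structure, not its robustness to every
instrumental artifact of real AFM data.

## FX analysis

**Peak detection** scans the median-smoothed force left to right and commits
the running maximum as a rupture candidate when the force falls by
`min_drop` below it. The forward-drop rule (rather than topographic
prominence) keeps small intermediate peaks whose backward drop is shallow.
Each candidate must then be confirmed by a sample-to-sample extension jump
≥ 0.2 nm (0.1 nm in the classification pipeline) between the running maximum
and the drop trigger; the peak is snapped to the sample preceding the jump.
Rupture events in rapid succession blur into one smoothed force drop but
keep separate jumps, and each jump is emitted as its own peak. The generic
defaults are min_force 20 pN and min_drop 10 pN over a 7-sample median; the
classification pipeline commits on 4 pN drops over a 3-sample median because
the jump validation removes the false positives that would otherwise flood
in. Late-domain ruptures produce drops of only ~13 pN (the WLC/cantilever
series stiffness falls as 1/Lc), which is why a 15 pN threshold is too
conservative for heptamer traces.

**Flank fitting.** Each peak's rising flank runs from the force minimum
after the previous rupture to 95% of the peak force, with both endpoints
located on a smoothed curve and the window taken as a contiguous index
range: selecting individual samples by their noisy force value censors the
noise distribution and biases the fit (this effect alone shifted fitted
persistence lengths by several percent). Lc and p are first fitted jointly
per flank; p is then pinned to the value from the flank spanning the widest
force range (normally the first stretch rising from slack, the only window
in which p is well conditioned) and all flanks are refitted — one chain has
one persistence length. Flanks shorter than 10 samples are flagged
unfittable and carry a single-point fallback contour from inverting the WLC
at the apex; a least-squares mini-fit on a handful of noisy samples is
strongly right-skewed, the one-point inversion is not. Noiseless traces are
recovered exactly (Lc, p to <1e-6 relative; peak forces bitwise).

**Cascade grouping and classification.** Events are grouped into per-domain
cascades on their contour lengths: an increment within the intermediate
acceptance window [3, 15] nm continues the current cascade, a larger one
starts the next domain, and the final group (tip detachment) only supplies
the previous domain's endpoint. n_states = rupture peaks + 1; a cascade
whose total release deviates from the expected per-domain total by more than
10 nm is flagged ambiguous and excluded from flux denominators. Two repair
rules resolve domain overlap, each triggered by a conserved-contour
signature: (i) a long-lived intermediate that outlasts the next domain's
native rupture fuses two domains into an overfull three-peak cascade
followed by a deficit single-peak cascade; (ii) two domains rupturing within
one sample fuse into a single overfull peak. Both are rewritten into the two
underlying domains. Flux percentages are computed over unambiguous domains;
standard errors come from a nonparametric bootstrap that resamples whole
traces with replacement (500 resamples), preserving within-trace
correlation. The difference in ΔLc between groups is tested with a
two-sided permutation test on the mean difference (the add-one rule keeps
p > 0); 1e5 permutations resolve p down to 1e-5.

At the study conditions (500 heptamer traces, 5 pN noise), the pipeline
recovers the 3-state flux to within ~2 percentage points of the generated
truth (inside three bootstrap SEs), and the ΔLc medians to ≤0.2 nm. The
residual deficit is irreducible at the trace level: ruptures that coincide
within one sample carry a single extension jump.

## Contour accounting

Expected total contour gain: (n_residues − sequestered) × 0.36 nm/aa −
folded end-to-end distance. Disulfide sequestration follows the plain
index-difference convention (Cys3-Cys26 → 23 residues), matching the
published arithmetic for azurin ((128−23)·0.36 − 1.4 = 36.4 nm); an
inclusive count would give 24. Folded end-to-end distances use Cα
coordinates. The sequestration shift between an unconstrained and a
metal-constrained pull is read off as the difference of the final plateaus
(median over the last 10%) of the anchor-pair separation series.

## Coarse-grained pulling

One bead per residue, structure-based (Gō-type) force field: harmonic
backbone bonds (k = 50 kcal/mol/Å²; r0 native), 12-10 contact wells between
Cα pairs within 8 Å and ≥3 residues apart (ε = 5 kcal/mol), r⁻¹² repulsion
(σ = 4 Å) for all remaining pairs, optional harmonic disulfides. The copper
is an explicit bead tied to the Cα beads of its five ligand residues by
harmonic springs with equal spring constants (default 25 kcal/mol/Å²;
equilibrium distances from the input structure); the "no_axial" variant
constrains only the three equatorial ligands (His46, Cys112, His117),
leaving Gly45 and Met121 free. At one-bead resolution the ligand *atoms*
cannot be placed; what the model preserves is the constraint topology —
which residues the copper ties together — which is what drives chain
sequestration. Copper nonbonded terms are omitted.

Dynamics are Langevin via BAOAB splitting (dt = 0.005 reduced time units,
chosen by stability sweep against the stiffest bond; friction 1 γ/τ;
T = 150 K default — low enough that rupture order is sharp against thermal
noise). With zero friction the integrator is velocity Verlet and conserves
energy to <0.1% of |E| over 1e5 steps. One terminal bead is fixed; a dummy
anchor moves at constant velocity (default 0.05 Å/τ) along the initial
end-to-end axis and drags the other terminus through a 7 kcal/mol/Å² spring
whose stride-averaged elongation is the reported force. The pulling speed is
deliberately orders of magnitude above all-atom practice so that a full pull
takes seconds on one core; force magnitudes are qualitative by construction.
The thermal-noise stream always spans n_residues+1 beads so that runs with
and without the copper bead share per-residue noise, making same-seed
comparisons meaningful.

On the packaged 8-strand barrel fixture, strand pairs separate sequentially
from the pulled C-terminal side (GC-GC distance-change threshold 0.5 nm,
between the ~1.5 nm excursions of broken pairs and the <1 nm breathing of
intact ones). The copper imprint is quantified by the **curtailment
extension**: the first crossing of a 2000 pN reference force on the
median-smoothed trace — the position of the coordination-sphere wall, this
fixture's analogue of the second transition-state peak. The bare construct
never reaches that force before essentially full extension, discrete
"second peaks" are not robustly separable from strand-peel bumps across
seeds, and the wall position orders exactly as the physics dictates
(medians over 10 seeds): full sphere k=100 (9.09 nm) < k=25 (9.18) <
k=5 (9.56) < equatorial-only (10.11) < k=1 (10.72) < bare (11.95). Soft
spheres (k < 25 kcal/mol/Å²) thus stay close to the bare behaviour, and the
equatorial-only variant lies between the bare and fully constrained cases.

Controlled rupture deletes all active coordination bonds simultaneously at
a prescribed extension. These comparisons run athermal (T = 0, damped):
with thermal noise, chaotic decoherence makes same-seed trace differences
meaningless. Released before the second resistance (4 nm), the remainder of
the trace matches the bare pull of the same seed to <75 pN on a ~500 pN
force scale; released at or beyond it (6, 7, 8 nm), a new force peak
appears whose position (5.9/6.7→8.2 nm) is non-decreasing in the release
extension.

## TCSPC reconvolution

The model decay is the discrete convolution of the (shifted, unit-area) IRF
with I(t) = Σ αᵢ exp(−t/τᵢ), evaluated by the per-channel recursion
y[k] = y[k−1]·exp(−Δt/τ) + R'[k] (implemented as an IIR filter; identical to
the direct convolution sum to machine precision). The shift δ is a
continuous fractional-channel parameter applied to the IRF by linear
interpolation. Fits minimise Poisson-weighted least squares
(weights 1/max(counts, 1)) with Levenberg-Marquardt over the window from
the decay peak to 0.1% of the peak count; amplitudes are free non-negative
parameters renormalised to fractions, lifetimes are reported ascending, and
the fit is multi-started from three lifetime spreads because a single bad
initialisation can land in a local minimum. Non-convergence returns a
flagged result, never a silent one. τ_m = Σ αᵢτᵢ. At the 5000-count
acquisition floor, τ_m is recovered to ~3% median error; for
three-exponential decays a flat amplitude-degeneracy direction wobbles a
single fit's τ_m by a few percent at unchanged χ², so summary values are
medians over repeat acquisitions.

## Known limitations

* Classification accuracy is quoted for the generator's statistical
  structure; real traces add extension noise and adhesion artifacts that
  would weaken the extension-jump validation (it can be disabled, at the
  cost of the resolution of rapid successions).
* The interleave-repair rules only resolve the two most common overlap
  signatures; deeper interleaves (an intermediate outliving two or more
  foreign natives) remain misassigned and are the main residual flux bias.
* The simulator reproduces rupture order and constraint topology, not force
  magnitudes, barrier heights or solvent effects; its barrel fixture is a
  generic up-down barrel, not the azurin Greek-key fold.
* Problem sizes used by the test suite and the acceptance script (500/300
  traces, 5-10 pull seeds, 1e5-count decays) were chosen so the full
  analysis reruns in minutes on one core.
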