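# Methods

This note records the models, parameter choices and numerical decisions
behind `airemboli`, and what the synthetic-data tests do and do not
demonstrate about real intra-operative recordings.

## Acoustic forward model and sizing

A detected embolic signal carries one number, the measured embolus-to-blood
ratio MEBR = 10·log10(I_E+B/I_B) in dB. The forward model predicts it as

    MEBR(d) = 10 log10[ σ_b(d, f) / (η(H, f) · V_s) ],

with three ingredients:

**Bubble cross-section σ_b.** Plane-wave scattering by a fluid (air) sphere
in blood, solved by matching pressure and normal velocity at the interface
and summing partial waves; the backscatter cross-section is defined as
4π|f(π)|², so a perfectly reflecting sphere approaches its geometric area
πa² at large ka. Host blood: ρ = 1055 kg/m³, c = 1570 m/s; gas: ρ = 1.204,
c = 343. Two dissipative corrections make the curve strictly increasing on
the sizing domain, which the inversion requires:

* the interior wavenumber is complex, with loss tangent
  0.05 + 0.45·(2.5 um/a)² — a constant gas-absorption floor plus a thermal
  boundary-layer term that grows toward resonance size. The lossless
  solution has high-Q gas-cavity resonances (8–12 dB notches, well under a
  micron wide) that physically damped bubbles do not show;
* backscattered *power* is averaged over a 12% fractional transmit
  bandwidth (15 points), washing out the geometric interference ripple of a
  strong scatterer at mm sizes.

With both corrections the curve is strictly monotone on [5 um, 4 mm] at
2 MHz (checked on a 4000-point log grid), matches the long-wavelength
above-resonance closed form 4πa²/((f_r/f)²−1)² within ~1% at 10 um, and is
within 1% of the geometric cross-section at 3 mm. The public function
serves values from a cached 3500-point log-log table (interpolation error
~2×10⁻⁴ in recovered diameter). Below ~5 um the curve folds over at the
Minnaert resonance (~3.2 um at 2 MHz), so 5 um is the sizing floor; the
table extends to 2 um for the synthetic generator only, so that sub-floor
bubbles can emit their physically weak signals.

**Blood backscatter η.** Incoherent red-cell scattering: number density
H/V_cell times the single-cell Rayleigh cross-section (V_cell = 90 fL,
κ_cell = 3.41e-10 Pa⁻¹, κ_plasma = 4.09e-10 Pa⁻¹, ρ_cell = 1092,
ρ_plasma = 1021 kg/m³) times the packing factor (1−H)⁴. H(1−H)⁴ peaks at
H = 0.20 and varies by ~1.5 dB across the intra-operative range 0.22–0.37,
within the ≤5 dB sensitivity that motivates correcting MEBR for measured
haematocrit. The inversion uses the haematocrit in effect at each event
time directly, which is equivalent to normalising the MEBR to a reference.

**Sample volume V_s.** A cylinder: vessel cross-section times the axial
sample length mapped onto the vessel, L_s/cos θ. The 1/cos θ elongation is
capped at a factor of 2 so that extreme angles cannot inflate the volume
without bound; at the default θ = 30° the cap is inactive, and doubling the
sample length lowers MEBR by exactly 3.01 dB. Defaults: f = 2 MHz,
L_s = 10 mm (valid range 8–12), θ = 30°, detection threshold 7 dB.

**Inversion.** Bisection of the forward model over [5 um, vessel diameter]
(Brent's method, 0.01 um tolerance; a vectorised 60-step bisection for
batches). Round-trip error is ≤0.1% across the domain. MEBRs below the
floor value clamp to 5 um and above the ceiling to the vessel diameter,
both flagged rather than raised — real streams contain weak and saturated
signals. Every sized bubble carries a 40% relative diameter uncertainty,
the assumed sizing error for beam-vessel misalignment, and a volume
V = (4/3)πr³.

A physical consequence worth stating: above resonance the cross-section
rides the ~4πa² plateau, so the MEBR-diameter curve averages only
~18 dB/decade. Sizing is therefore intrinsically soft — a 1 dB measurement
error is ~13% in diameter — and no inversion scheme can be much sharper
than that; the package's robustness test measures exactly this limit
(~49% of bubbles within 10% under 1 dB noise plus geometry jitter).

## Event pipeline

Signals below 7 dB above background are dropped (threshold inclusive,
applied to the measured MEBR before any haematocrit normalisation). Showers
are runs whose rate in a sliding 1 s window exceeds 5 emboli/s; all members
share the background reference taken just before onset, and runs split at
gaps wider than the window. Curtain intervals (showers too dense to resolve
individual signals) are merged if overlapping, their events flagged and
excluded from sizing and simulation; only durations are reported.
Haematocrit between 3-minute samples is last-observation-carried-forward.
Per-event sizing failures are flagged and skipped, never fatal: an
intra-operative stream must not abort on one bad record.

## Dissolution

Quasi-static Epstein–Plesset shrinkage with the transient diffusion-layer
term dropped:

    dr/dt = −(D·L/r) · (1 − f + 2σ/(rP)) / (1 + 4σ/(3rP)).

Defaults: D = 2e-9 m²/s, Ostwald solubility L = 0.017, ambient
P = 101.325 kPa, surface tension σ = 0.056 N/m, and saturation fraction
f = 0.99. Blood is treated as a single "air" gas pool; multi-gas exchange
and perfusion-limited corrections for lodged bubbles are out of scope (the
shared shrink law keeps the obstruction estimate an upper bound). The
near-saturation default is a calibration: arterial blood on bypass is close
to gas saturation, and with f = 0.99 the model clears a 38 um bubble
(the bypass filter size) in 57 s while a 1 mm bubble takes 74 h — the two
anchor behaviours of the model. Dissolve time integrates dt/dr by adaptive
quadrature; with σ = 0 it reduces exactly to r₀²/(2DL(1−f)), which the
tests use as an analytic oracle. Saturated blood with zero surface tension
has no dissolution drive and returns +∞.

## Vascular tree and Monte-Carlo transport

The MCA territory is a symmetric binary tree: generation-g diameter
root·2^(−g/3) (Murray's law), length 20 diameters, Poiseuille resistance
128 μL/(πd⁴) with μ = 3.5e-3 Pa·s, driven by 100 mmHg at the root against
0 at every terminal outlet. Nineteen generations below the root give
524,288 terminal arterioles (~30 um for a 2.6–3.5 mm root), matching the
reported ~500,000; a 20-generation variant reaches ~26 um terminals and the
depth is configurable (guarded at 24). Tree depth, vessel length ratio,
outlet pressure and viscosity are package choices where the source
literature is silent; none of them affects flow splits in the unobstructed
symmetric tree, only lodging depths and pressure profiles.

**Exact sparse flow solve.** Only vessels on paths to blockages are
materialised; every untouched subtree collapses to a closed-form effective
resistance (per-level resistance is constant under Murray scaling, so a
pristine depth-G subtree is just a sum). Effective resistances propagate
leaf-to-root, pressures and flows root-to-leaf; flow anywhere in a pristine
region is the nearest materialised ancestor's flow halved per generation.
The solve is exact: it matches a dense nodal linear system to machine
precision on depth-6 trees with random blockages, and terminal flows sum to
the root flow to 1e-16 relative under any blocked set.

**Embolus dynamics** (time step 0.1 s): free emboli advance at the local
mean speed Q/A, possibly crossing several vessels per step; at each
bifurcation the daughter is drawn with probability proportional to daughter
flow (exact ties are a fair coin; two dry daughters halt the embolus). On
entering a vessel narrower than its equivalent sphere, a bubble deforms
into a cylinder with hemispherical caps; contact area
A_wall = 2πr·(V − (4/3)πr³)/(πr²) and it lodges iff stiction balances the
pressure force across the blocked vessel, K·A_wall ≥ Δp·πr², with
K = 10 N/m². Δp is the upstream nodal pressure of the hypothetically
blocked vessel minus outlet pressure (a blocked subtree carries no flow, so
it floats at outlet pressure). All emboli shrink by the dissolution law
each step; lodged ones are re-checked and remobilise when the criterion
fails, travelling deeper — accumulation and clearance, not permanent
plugs. Emboli under 1 um radius are removed. At a terminal outlet a bubble
larger than the lumen impacts geometrically and blocks until it shrinks
below the lumen; a smaller one parks there and dissolves without blocking
(the capillary bed is impassable to bubbles, and stiction alone would
otherwise let them leave the tree). A long deformed bubble is treated as
residing in its entry vessel even when its contact length exceeds the
vessel length; neighbouring generations are similar enough in calibre that
this keeps the criterion honest without multi-vessel bookkeeping.

Under these rules the stiction balance, not an assumption, decides where
bubbles stop: with a 2.6 mm root, a 3.5 mm bubble lodges around generation
8 (the 100 mmHg head overwhelms stiction any higher), 1 mm around
generation 12, 500 um around 15, and only bubbles over roughly the terminal
calibre can obstruct terminals. Lodging depth is monotone in bubble size,
and sub-38-um showers are benign (<0.05% of terminals) — both asserted in
tests.

**Monte-Carlo ensemble.** Each injected bubble's radius is multiplied by
log-normal noise of relative SD 0.40 (mean 1), the assumed sizing
uncertainty; routing adds path randomness. An ensemble (default 30 runs,
seeds spawned deterministically from one seed) yields the mean and a
2.5/97.5-percentile 95% band of the percentage of unperfused terminals at
every step. Left and right MCAs are independent trees. Buoyancy is
neglected and the tree symmetrised, so obstruction estimates are upper
bounds by construction. Bubbles cannot coalesce.

## Synthetic operations

The generator emulates the statistical shape of intra-operative streams:

* stage structure pre-CPB / CPB / post-AxC / post-CPB with Poisson base
  rates plus shower bursts at stage onsets; expected event share before
  cross-clamp removal is exactly 73%;
* per-stage log-normal diameters, log-sd fitted from quartiles
  (ln(q3/q1)/(2·0.6745)): median 28 um, IQR 17–51 (log-sd 0.814) during
  bypass; median 72 um, IQR 28–202 (log-sd 1.465) after cross-clamp
  removal. The mixture median is ~33 um and ~85% of bubbles are below
  100 um, the distribution the sizing pipeline is expected to recover;
* bilateral showers share onset times with independent per-side draws;
  valve/combined protocols carry ~2–2.4× the CABG load and can emit
  curtain intervals (which contain no discrete events, matching what an
  observer could record);
* haematocrit is a clipped random walk in 0.22–0.37 on a 3-minute cadence;
  MCA diameters are uniform on 2.6–3.5 mm; blood pressure hovers near
  100 mmHg;
* synthesis jitters each event's sample length (8–12 mm), Doppler angle
  (±10° around 30°) and adds 1 dB Gaussian MEBR noise by default; events
  below the detection threshold are emitted anyway, since filtering is the
  pipeline's job.

What passing these tests shows: the pipeline undoes its own forward model
faithfully, calibrations are self-consistent, and recovery degrades the way
the acoustics says it must. What it does not show: performance on real
recordings, where artefact rejection, probe drift, non-Gaussian backgrounds
and solid emboli (which this model would misclassify as small bubbles) all
live outside the synthetic family.

## Statistics

Quartiles use the inverse-empirical-CDF convention (order statistics at
ceil(n/4), ceil(3n/4)); count medians are reported rounded half-up with the
exact value retained. The rank-sum test uses midranks, a tie-corrected
normal approximation, no continuity correction, and is signed by the first
group's rank-sum deficit. Group summaries report medians and means side by
side, since the two diverge badly in small skewed cohorts. Threshold
fractions ("less than 100 um", "larger than 500 um") are strict
inequalities. p-values are descriptive, not gatekeeping; no
multiple-testing control is applied to the two tests reported.

## Reproducibility and problem sizes

Every stochastic component takes a seed; ensembles spawn per-run seeds from
it; pipeline outputs embed the seed and a configuration hash, and identical
seed+config reruns are byte-identical. The default test run keeps
simulations at the scale a laptop handles comfortably: property checks on
depth ≤ 8 trees against dense oracles, full-depth (19-generation) runs with
~1,500 bypass bubbles plus tens of macrobubbles over a few hundred seconds
of surgical time, and 10,000-event sizing streams. A full-depth,
full-ensemble patient reconstruction is minutes per run and parallelises
trivially across ensemble members.

## Known limitations

Single-gas dissolution without perfusion limitation; Newtonian blood; a
symmetric tree with no anatomy, autoregulation, oxygen transport or
collateral flow; no buoyancy (upper-bound stance); no bubble coalescence;
no solid-embolus discrimination; sizing undefined below 5 um by physics,
soft everywhere by the plateau argument above; curtains contribute duration
only, so patient totals during curtain-heavy surgery are underestimates.
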