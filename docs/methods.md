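# Methods

## Kinetic model

The complex is modelled as a three-pathway, two-binding-mode network. A
trajectory starts by drawing the binding mode: A (strong) with probability
`p_mode_a = 0.8`, B (weak) otherwise; modes never interconvert under load.
In mode A two transitions compete — complex rupture (pathway P1) and XMod
unfolding; if XMod unfolds the system enters a weakened state whose only
exit is low-force rupture (P2). Mode B has a single rupture transition
(P3). Two ddFLN4 fingerprint domains unfold independently, each in two
sequential sub-steps; fingerprints certify single-molecule tethers and
shape the loading path but do not gate any rupture.

Every transition is a Bell–Evans (BE) barrier crossing,
`k(F) = k0 exp(F Δx‡ / kBT)`. Default parameters (k0 in 1/s, Δx‡ in nm)
are the AFM-SMFS estimates for the Rc XMod-Doc:Coh system:

| process                  | k0       | Δx‡   |
|--------------------------|----------|-------|
| P1 rupture (XMod intact) | 4.70e-8  | 0.178 |
| XMod unfolding, measured | 9.94e-6  | 0.139 |
| XMod unfolding, corrected| 4.53e-5  | 0.116 |
| P2 rupture (XMod open)   | 7.43e-4  | 0.277 |
| P3 rupture (mode B)      | 2.79e-5  | 0.366 |

The simulator defaults to the *corrected* XMod set — the best estimate of
the intrinsic process once the observation bias (rupture censors
unfolding) is removed; the measured set is selectable. DHS parameter sets
(ν = 0.5: P1 ΔG‡ = 22.8 kBT, P3 ΔG‡ = 8.46 kBT) are packaged for the
off-rate fitting stage.

## Constant-speed pulling simulation

Force ramps are generated on an even molecular-extension grid (default
step 0.05 nm) from the Marko–Siggia WLC interpolation with persistence
length 0.4 nm (typical unfolded polypeptide; not a printed value, exposed
in config). Extension is converted to AFM head height through the
cantilever bending correction `H = X + F/k` (spring constant default
100 pN/nm = 0.1 N/m, inside the usual 0.07–0.1 N/m calibration range), and
time follows from the constant head speed, `t_{i+1} = t_i + ΔH/V`. In each
time slice every active transition fires with probability
`1 − exp(−k(F)Δt)` against an independent uniform draw; simultaneous
firings are resolved proportionally to the instantaneous rates. The slice
scheme's discretization error is O(Δt²); halving the grid step moves the
most probable rupture force by well under 1 pN (tested).

Unfolding adds the transition's contour-length increment; because the
head is effectively stationary on the unfolding timescale, the new
extension is found by solving `x + F(x; Lc+ΔLc)/k = H` (the force drops,
the extension jumps forward). Rupture zeroes the force; a short zero-force
tail is emitted so that rupture detection in the analysis stage sees the
drop to baseline. Curves that reach the maximum head height (default
400 nm) or a 2500 pN safety cap without rupturing are flagged
``no-rupture``.

The folded-system contour length (tethers, linkers, folded domains)
defaults to 180 nm. It is not printed anywhere; it controls the absolute
loading-rate scale (a realistic several-hundred-nm construct) but not the
rate laws, and it is a config field. Fingerprint sub-step kinetics are
likewise not printed; the defaults (k0 = 3e-3 1/s, Δx‡ = 0.45 nm and
k0 = 1e-3 1/s, Δx‡ = 0.50 nm; increments 15 + 17 nm per domain) place the
unfolding events between roughly 60 and 120 pN at the simulated speeds —
the fingerprint role — and are fully configurable.

One root seed spawns an independent child stream per curve
(`numpy.random.SeedSequence`), making batches byte-identical for a given
seed regardless of chunking.

Force-clamp mode runs the same network at fixed force as a competing-
hazard (Gillespie) simulation. Because every process is slip, the network
lifetime is monotone non-increasing in the clamp force — the catch
behaviour exists only under force ramps.

## Curve analysis

Recorded curves are transformed to contour-length space with the
freely rotating chain (FRC) model: bonds of length b = 0.11 nm at fixed
angle γ = 41° (the standard polypeptide convention; neither value is
system-specific). The transform has three asymptotic regimes selected by
the reduced force F·b/kBT against b/l and l/b (l = FRC persistence
length ≈ 0.366 nm, Kuhn length a ≈ 0.840 nm):

* `F·b/kBT < b/l` — linear response, `L = 3 kBT x/(F a)`. The printed form
  of this regime is dimensionally inconsistent in its source; the standard
  low-force limit is implemented. These samples are additionally excluded
  from plateau analysis (model error dominates there).
* intermediate — WLC-like, `L = x/(1 − (4Fl/kBT)^{-1/2})`;
* `F·b/kBT > l/b` — discrete FRC, `L = x/(1 − (2Fb/kBT)^{-1})`.

The two upper branches join continuously at the boundary. Only samples
above a 10 pN force floor are transformed.

Plateau detection is histogram-based: 1 nm bins, light Gaussian smoothing
(σ = 1 nm), peak finding with a relative prominence threshold (4% of the
histogram maximum, minimum 3 counts) and a 10 nm minimum separation
(below the smallest modelled sub-step, above the satellite structure that
the WLC→FRC model mismatch produces inside one plateau). The histogram is
zero-padded so terminal plateaus at the edge of the recorded range are
found. Increment sizes are differenced *at matched force*: each pair of
adjacent plateaus is restricted to its common force band and the medians
are differenced, cancelling the force-dependent model bias of the
transform (both plateaus sample the same transform factor). This recovers
the 64 nm double-fingerprint total to ±0.3 nm on simulated data, where
raw peak spacing carries a ~2% bias.

Curves are accepted as single-molecule tethers when exactly four
sub-step-sized increments (11–21 nm) totalling 64 ± 6 nm are present.
Classification: P2 when an XMod-sized increment (34–42 nm window, covering
the 37 nm expected and 38 nm observed values) precedes rupture; otherwise
P1 vs. P3 by a 350 pN threshold — midway between the ~200 and ~500 pN
rupture modes, configurable, with a two-component posterior assignment as
the documented alternative for ambiguous regimes. Rupture force is the
last sample before the terminal drop to baseline; loading rate is the
slope of force against time over the final 5 nm of extension (never
reaching back across an earlier unfolding drop). On 1000 simulated curves
per speed this pipeline classifies ≥97% of curves identically to the
simulator truth.

## Off-rate reconstruction and fitting

Rupture/unfolding force histograms use equal 40 pN bins from 0; each
bin's loading rate is the mean over its events (the estimator is not
specified by the source analysis; the mean is the obvious choice and is
configurable in spirit — the KDE route avoids binning altogether). The
histogram transformation maps bin k to
`k_off(F_k) = h_k r(F_k) / ((h_k/2 + Σ_{i>k} h_i) ΔF)` with
`h_k = C_k/(C_tot ΔF)`; zero-count bins are skipped and the last occupied
bin's denominator reduces to `(h_k/2)ΔF`. The continuous form divides the
KDE density times the loading rate by the survival, truncated when
survival < 1e-3 (tail instability). Off-rate curves from different speeds
are averaged per force bin, requiring at least two speeds per bin.

Most probable forces per speed come from a Gaussian fit of the force
histogram (Freedman–Diaconis-style bin width, KDE mode as fallback); BE
fitting is ordinary least squares of F* on ln r. DHS fits minimize
weighted residuals in log k (off-rates span decades) over
(log10 k0, Δx‡, ΔG‡) with bounds, initialized from the BE trend; on
noiseless self-generated curves all three parameters are recovered to
better than 1e-4 relative error. The DHS domain constraint
(νFΔx‡ < ΔG‡kBT) raises an error rather than clamping, so fitting code
must bound its search region — silent clamping corrupts least-squares
gradients.

### XMod censoring-bias correction

Observed XMod unfolding statistics are censored: unfolding that would
occur above the complex's rupture force is never seen, which flattens the
apparent speed dependence (naive Δx‡ too large, k0 too small). With the
complex-rupture parameters held fixed, the correction adjusts
(log k0, Δx‡) of the unfolding process by Nelder–Mead so that the
predicted fraction of strong-mode curves showing unfolding matches the
observed fraction at every speed. The prediction integrates the two
competing hazards deterministically along the same WLC loading path the
simulator uses, with the slice-exact allocation
`S_i (1−e^{−(k_u+k_r)Δt}) k_u/(k_u+k_r)`; this is the exact expectation a
nested Monte Carlo objective would estimate, but smooth and noise-free, so
the simplex converges reliably and the whole correction is deterministic
given the data. Given exact fractions it recovers the generative
parameters to optimizer precision; at realistic sample sizes the joint
(k0, Δx‡) estimate moves along a likelihood ridge, with Δx‡ the robustly
identified coordinate.

## smFRET stage

Burst search follows the sliding-window convention: a photon qualifies
when ≥4 photons fall in the 500 µs window centered on it; contiguous
qualifying runs with ≥40 photons are bursts. Constant per-channel
background rates (config inputs, default 0) are subtracted over each
burst's duration. The stoichiometry formula is the standard ALEX
convention `S = (γI_DD + F_DA)/(γI_DD + F_DA + I_AA)` with F_DA the fully
corrected donor-excitation acceptor signal; the doubly-labeled selection
keeps 0.2 ≤ S ≤ 0.8. Additional kinetics-based filters (photobleaching /
blinking rejection) are supported through a pluggable burst-filter hook
but are not part of the default pipeline. Efficiency histograms (bin
width 0.025) are fitted with one- or two-Gaussian least squares on bin
centers.

The synthetic generator draws burst sizes as 40 + Poisson (mean 80
photons, matching the burst-search threshold and a typical confocal
burst), splits photons multinomially across DD/DA/AA so the corrected
efficiency and stoichiometry hit their targets in expectation, and mixes
populations by the requested fractions. Default corrections α = 0.05,
δ = 0.10, γ = 1.0 are representative magnitudes for a green/red dye pair
(the study's own factors are not published); the generator/analysis round
trip is unbiased for any corrections in the tested grid. A Förster
relation `E = 1/(1+(d/R0)^6)` is provided for generator use only — R0 for
the dye pair is not published, so distances are never asserted, only the
monotonicity that the 3.5 nm (mode A) dye separation outshines the
4.9 nm (mode B) one.

## What the synthetic data does and does not emulate

The generator reproduces the kinetic scheme, WLC loading paths, the
cantilever bending correction, fingerprint patterns and two-population
FRET mixtures. It deliberately omits thermal force noise, cantilever
hydrodynamics and drift, calibration spread, refolding, and unassigned
partial-unfolding events — all instrument or sample realities outside the
model. Consequences to keep in mind:

* Simulated rupture-force distributions are clean first-passage
  distributions (width ≈ kBT/Δx‡, 15–30 pN). Experimental histograms are
  substantially broader. The combined P1/P2 off-rate curve is therefore
  non-monotonic with a sharp local maximum just above the P2 rupture mode
  (~215 pN at the simulated speeds), and its decreasing (catch) regime
  spans roughly 215–400 pN. Broader experimental distributions push the
  apparent maximum higher into that regime (reported near 300 pN for this
  system); the location of the *onset* of the decrease is therefore the
  quantity most sensitive to the idealized noise model, while the
  existence and extent of the decreasing regime are robust.
* The FRC transform applied to WLC-generated curves carries a small
  force-dependent bias (<0.5% of contour length in the analysis band);
  the matched-force differencing above removes it from increments.
* Passing recovery tests here demonstrates correctness of the estimators
  under the model's assumptions, not robustness to instrument artifacts.

## Problem sizes and runtime

The packaged study conditions are 1000 curves per speed at
{100, 400, 1600, 6400} nm/s; the full simulate-analyze-fit cycle runs in
roughly 20 s on one CPU, and the test suite (including one full-scale
batch, shared across tests) in under a minute. Force-clamp statistics use
1000 replicas per force. Parameter-recovery replicate tests use reduced
batches (250 curves, three speeds per replicate) — sized so the tested
direction effects are well above sampling noise.

## Known limitations

* Only BE rate models drive the default network; DHS-driven simulation is
  supported at the transition level but not exercised by the defaults.
* k0 estimates from loading-rate fits are zero-force extrapolations over
  many decades; expect order-of-magnitude accuracy, and rely on Δx‡.
* The P1/P3 threshold classifier assumes well-separated rupture modes; at
  loading rates far outside the study range the 350 pN default would need
  revisiting (it is a config field).
* The FRC low-force branch is excluded from plateau analysis; traces that
  never exceed ~11 pN are effectively unusable, matching practice.
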