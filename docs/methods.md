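# Methods

## The problem and the approach

A continuous-wave ESR spectrometer records the field-modulated first
derivative of microwave absorption against the swept magnetic field.
Hyperfine interactions split the resonance into multiplets: `n` equivalent
nuclei of spin `I` produce `m = 2nI + 1` lines spaced by the coupling
constant `A` (gauss), with multinomial intensities.  When line broadening
exceeds the splitting, the multiplet is invisible in the recorded spectrum,
and simulation-based fitting becomes initial-guess-dependent and fragile.

`esrwpt` takes the simulation-independent route: decompose the spectrum
with a wavelet packet transform (WPT), pick the tree node whose frequency
band contains the hyperfine comb, and read the coupling directly from the
evenly spaced oscillation of that node's reconstruction.  Everything the
package reports — couplings, nuclear counts, g values, mixture verdicts —
is derived from peak *positions*; component intensities are known to be
unreliable after band-passing and are never used quantitatively.

## Wavelet engine

The spectrum is resampled to the median field step, padded symmetrically to
the next power of two, and decomposed with an orthogonal periodized filter
bank (db9 default; db6 and coif3 supported).  Periodization keeps the
transform orthogonal: coefficient vectors have exactly `p / 2^level`
entries, per-level node reconstructions sum to the input, and energy is
conserved to machine precision.  The symmetric padding happens once,
upstream, where it prevents the edge discontinuities of a derivative
spectrum from bleeding into the detail components; inside the filter bank
periodization is what preserves the exact-reconstruction algebra.

Node paths are root-to-leaf over `{A, D}`; `paper_name` renders the
newest-filter-first style common in the spectroscopy literature
(`"AAD"` = `DAA3`).  Packet nodes in natural order are not frequency
ordered — `node_band` maps a path to its nominal band through the
binary-reflected Gray code.  The decimated transform is not shift
covariant; peak spacings, which are what the analysis consumes, are
unaffected.

## Component selection

Level-1 detail is treated as noise and the D1 subtree is never analyzed.
Fixed mode applies the default recipe for unresolved spectra: level 4,
envelope `AAAA`, structure node `AAD` (the level-3 detail) or its
approximation child `AADA`.  Auto mode scans levels 3..N−1 bottom-up and
returns the first candidate carrying a *credible* even multiplet.
Credibility matters because band-passed noise oscillates quasi-periodically
at any band's characteristic frequency; a candidate group must pass all of:

* **in-band**: its implied ripple frequency `1/spacing` lies inside the
  node's nominal band;
* **dominant-frequency agreement**: the spacing matches the node's own
  spectral maximum within 25% (noise can interleave extra peaks and halve
  a run's apparent spacing);
* **raw-lobe support**: the raw spectrum's power spectrum shows a local
  lobe at that frequency — 3× above the surrounding continuum, with the
  local power maximum within 10% of the group frequency — and no ≥5×
  stronger lobe at half the frequency (second-harmonic alias);
* **on-line**: the group sits within its own span (or 5 spacings) of a
  peak of the envelope reconstruction — structure rides on resonance
  lines, noise is everywhere;
* **above the noise floor**: group amplitude ≥ 4σ·2^(−depth/2), with σ
  estimated from the D1 node;
* **more than minimal**: a ≥4-line group, or two groups concordant in
  spacing within 10% (the same comb under another coarse line).

When both the detail node and its approximation child qualify at a level,
the child is preferred (one more level of separation from the envelope) but
only if its spacing agrees with the parent's within 7%; a child whose
half-band holds a spacing the parent does not confirm has latched onto
distorted edge content.  If no level qualifies, selection falls back to the
fixed level-4 recipe and says so (`rationale="fixed_default"`).

## Peak analysis

Peaks are local maxima of the signed component — an oscillatory multiplet
component has one maximum per resonance line, so consecutive maxima are one
coupling apart (extrema of |component| interleave maxima and minima and
would halve every spacing).  Positions are refined by 3-point parabolic
interpolation.

Evenness is judged by position consistency: a contiguous run of ≥3 peaks
is a multiplet when the rms deviation of its positions from the best-fit
uniform lattice is ≤ 8% of the spacing (`lattice_tol`).  This tolerates
the small alternating spacing distortion that residual filter harmonics
imprint on a genuine comb — which inflates the coefficient of variation of
consecutive spacings past any usable bound — while still rejecting
drifting or irregular runs.  The plain CV criterion (default tolerance
0.10) remains available and is the documented contract of
`find_even_groups` when no lattice tolerance is passed.

The reported fine coupling is the quality-weighted consensus of the
least-squares lattice slopes of concordant groups, where a group's quality
is its median absolute amplitude at the line positions times the number of
lines beyond three.  The lattice slope is insensitive to the alternation
distortion; averaging over the packets under different coarse lines
suppresses residual noise.

### Cu(II) quartet analysis

In a Cu(II) quartet (copper I = 3/2, lines h-1..h-4 separated by A(Cu))
each copper line carries an m-line nitrogen multiplet centered on it.  The
multiplets overlap except at the sweep edges, so the analysis uses the
lowest- and highest-field even groups: h-1 is anchored at the amplitude
maximum of the low group (edge lines rise toward the copper line as
1:2:3…, while ringing beyond the multiplet decays), h-4 at the maximum of
the high group, and the multiplicity is the count of lines outward from the
anchors above 15% of the anchor amplitude.  A quarter-period phase
correction is added to the anchors: a first-derivative lineshape lags the
absorption by 90°, so component maxima sit `spacing/4` below the true line
positions.  Then `A(Cu) = (h4 − h1)/3` and `g = 714.4773·ν[GHz]/B` with
`B = (h1 + h4)/2` (CODATA h/μB; the printed worked example 2.0427 from
3203/3314 G at 9.316 GHz validates the constant).  When the whole quartet
collapses into one long even run, it is split at its midpoint so the two
edges can be analyzed separately.

## Mixtures

Weighted spectra are summed on the coarsest common grid (no normalization
by default — mixing recorded spectra is raw summation; max-abs and
double-integral options exist because relative concentration only maps to
weight under equal per-spin intensity).  Component identification runs the
extraction per user-chosen field window and assigns each even group to the
component with the nearest reference splitting; the minor component counts
as detected when its group's splitting is distinct from the *observed*
splittings of the other components (difference > 5% of the larger — the
regime of interest separates 17 G from 16 G, about 6% apart).  Partial
multiplets (3–4 of m lines) are admitted; overlap routinely hides the rest.

`detection_limit_scan` additionally screens minor candidates against the
groups the pure major spectrum produces in the same window: a group whose
center and spacing already appear in the major alone is an analysis
artifact (gap ringing of the major's own multiplets), not a second
component.  This mirrors checking candidate features against the original
spectra, and it makes a spectrum mixed with itself yield a single-component
verdict at every ratio.

**Known limitation.**  When the minor component's splitting is close to
the characteristic period of the analysis band, band-noise or gap ringing
of the major can occasionally form an even group at a similar spacing
(roughly one seed in four at the conditions of the bundled panel).  Such
artifact groups are not phase-locked to any physical line lattice, and the
pure-component screen in the scan removes them; a single-spectrum analysis
without reference spectra cannot, and should be interpreted accordingly.

## Synthetic data

The simulator is first-order, isotropic and region-wise: a "g-parallel
manifold" is just another spin system placed at its resonance field.  It
does not do powder averaging, second-order shifts, relaxation or passage
effects, and must not be mistaken for a physics simulator; its purpose is
spectra with machine-readable ground truth in exactly the regime the
extraction addresses — locally regular multiplets around resonance fields.
Sticks come from the first-order rule with multinomial intensities
(validated against brute-force enumeration), are convolved with the first
derivative of a unit-area Gaussian or Lorentzian (peak-to-peak width
specified in gauss), summed over weighted systems, and topped with seeded
white Gaussian noise scaled to the clean signal's maximum.  Consequences of
passing tests therefore extend to real spectra only insofar as real
artifacts (baseline drift, modulation distortion, saturation) resemble
white noise — which they do not; the even-spacing criterion is the intended
defense, and the robustness tests probe exactly that.

### Benchmark presets and why their numbers are what they are

* **tempo_like / tempol_like** — X-band nitroxide at 9.33 GHz, g = 2.0061:
  a ¹⁴N triplet (16 G) with proton superhyperfine of 0.20 G (tempo-like)
  or 0.44 G (tempol-like), modeled as 16 equivalent I=½ protons (these
  radicals carry 12 methyl plus ring protons with couplings of the same
  scale; the effective equivalent count controls the multiplet envelope
  width).  Lorentzian lines at 1.25× the proton splitting — the narrowest
  broadening at which the superhyperfine no longer produces raw-spectrum
  peaks at the 5% prominence criterion, i.e. just past visual resolution;
  the oxygen-broadening the preset emulates is collisional and hence
  Lorentzian.  Sampling puts ~9.5 points per superhyperfine period (4096
  points over 86 G, or 94.6 G for the wider tempol multiplet), which
  places the comb mid-band in the level-4 approximation child — the regime
  the level-4 recipe expects and the choice an operator would make when
  hunting sub-gauss structure.  Default noise 2% of the signal maximum
  (SNR 50).
* **cuqu_like / cuqua_like** — g-perp quartets at 9.316 GHz:
  g = 2.0427, A(Cu) = 37 G with two nitrogens at 26.5 G, and g = 2.0411,
  A(Cu) = 23.3 G with three nitrogens at 21.3 G.  Gaussian lines of 16 G
  and 13 G peak-to-peak: partially resolved, the regime in which edge
  positions remain recoverable to a gauss or two.  256 points over
  3000–3560 G gives ~12 points per nitrogen period, placing the comb in
  the level-3 detail node.  At fully unresolved broadening the edge
  anchors shift by line interference and recovered couplings carry a
  5–10% systematic stretch; that regime is reported honestly by wider
  error bars, not hidden.
* **cuqu_full / cuqua_full** — the g-perp system plus a four-line
  g-parallel manifold (A∥(Cu) = 200 G and 150 G; nitrogen splittings 17 G
  and 16 G; amplitudes 0.5, linewidths 8 G and 6 G).  g∥ parameters are
  not printed anywhere for these compounds and were chosen once as
  realistic axial-Cu values with the minor component's lowest g-parallel
  multiplet centered in the gap between the major's — the spatial
  separation that makes minor-component detection possible at all.
* **mixture_panel** — the two full spectra mixed at 2:1, 4:1, 10:1 and
  20:1 (minor fractions 1/3, 1/5, 1/11, 1/21), each component rendered
  with 1% noise (SNR 100) as two independently recorded spectra would be.
  The analysis windows (2603–2679 G and 2706–2794 G) bracket the lowest
  g-parallel multiplet of each component, chosen by inspection the way an
  operator chooses regions of interest.

## Numerical choices

* Peak prominence threshold: 5% of the component's maximum within the
  analyzed window — high enough to exclude deep-level residual noise, low
  enough that a few-percent minor component survives.
* Lattice tolerance 8%, CV tolerance 10% (5% in mixture mode), minimum
  3 lines per group.
* Field unit is gauss throughout; inputs in millitesla must be converted
  (×10) before reading.
* Degenerate inputs: an all-zero component yields an empty peak list; a
  spectrum with no credible group anywhere returns
  `A_fine = None` with `provenance["status"] = "no structure resolved"` —
  failure is reported, never extrapolated.
* Windowed quartet analysis crops the spectrum (20 G margin) before
  decomposition so prominence and padding are local; mixture windows on a
  wide sweep analyze the full-sweep decomposition and restrict the
  component afterwards, which avoids heavy padding of narrow crops.
* Determinism: identical inputs give bit-identical trees and results; all
  simulator randomness flows through a single integer seed.

## Test and acceptance problem sizes

The bundled checks run on 256–4096-point synthetic spectra: twenty noise
seeds per nitroxide preset for recovery and wavelet-robustness, ten seeds
of the four-ratio mixture panel for the detection limit, and two hundred
random signals per wavelet for the exact-reconstruction identities.  These
sizes give seed-level reproducibility of every reported number at
interactive runtimes.
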