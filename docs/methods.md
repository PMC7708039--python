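# Methods

`fretscape` implements the solution-side analysis used to map the
conformational landscape of protein-bound DNA with a fluorescence-lifetime
(FLT) FRET probe pair, together with the geometric descriptors used to
characterize duplex distortion in coordinate models.  This note records
the models, the numerical choices, and what the synthetic inputs do and do
not emulate.

## 1. TCSPC decay model

A time-correlated single-photon-counting (TCSPC) measurement histograms
photon arrival times into `n_channels` equal bins across a `window`
(defaults: 4096 channels over 100 ns, matching a typical DeltaFlex-class
acquisition).  The expected count in channel *k* at time *t_k* is

```
mu_k = b + S * sum_i a_i f(t_k; tau_i),    f(t; tau) = exp(-t/tau) (t >= 0)
```

with `b` a uniform background (default 0), amplitudes `a_i` summing to 1,
and the scale `S` chosen so that `max_k mu_k` equals the target peak count
(default 10,000 — acquisition runs until the peak channel reaches this).
Channel times are bin centers with channel 0 at the instrument-response
peak (t = 0); recorded counts are independent Poisson draws of `mu_k`,
which is the exact counting statistics of TCSPC (not a Gaussian
approximation).

When a Gaussian instrument response of FWHM > 0 is declared, `f` is
replaced by its analytic convolution with a unit-area Gaussian
(`erfc` form), evaluated in a form that is overflow-safe for small
`tau`.  The default is a delta response: the decays of interest here have
lifetimes of 0.3–5 ns against instrument responses of tens of ps, and the
downstream inversion supports either mode (reconvolution when an IRF is
declared, tail fitting from the peak channel otherwise), so neither is
asserted as the "right" acquisition model.

Lifetimes at or beyond 10x the window are accepted with a warning: they
are indistinguishable from background over the observed range.

## 2. Maximum-entropy lifetime inversion

### Objective

The decay is inverted onto a fixed grid of `G` lifetimes (default 120
points, logarithmically spaced over 0.02–20 ns, bracketing both the
sub-ns high-FRET lifetimes and the ~5 ns unquenched donor lifetime) by
minimizing

```
C(alpha) = chi2(alpha)/2 - lambda * S(alpha),   alpha_i >= 0
```

where

* `chi2 = sum_k (y_k - mu_k(alpha))^2 / sigma_k^2`, with
  `sigma_k = sqrt(max(y_k, 1))` and
  `mu_k = b + sum_i alpha_i K(t_k, tau_i)` (`K` the exponential kernel,
  IRF-convolved when the trace declares one; `b` a non-negative flat
  background fitted as one extra kernel column);
* `S(alpha) = sum_i [alpha_i - m_i - alpha_i ln(alpha_i / m_i)]` is the
  Shannon–Jaynes entropy against a flat prior
  `m_i = (total counts) / G` — maximal (zero) at `alpha = m`, so the
  entropy pulls the solution toward featurelessness and `lambda` sets how
  much structure the data must earn.

Positivity is enforced by the substitution `alpha = exp(u)`; the smooth
unconstrained problem is minimized with L-BFGS-B using the analytic
gradient.  The chi-square is evaluated through its normal-equation form
(`G = K'WK` precomputed), which makes one optimizer iteration O(G²)
instead of O(channels x G) and lets the solver run to tight tolerances
(relative objective change below 1e-12, up to 20,000 iterations) in well
under a second per solve.

### Reduced chi-square normalization

A 100-ns window at these lifetimes is mostly empty tail, and with
`sigma_k = sqrt(max(y_k, 1))` an empty channel contributes essentially
nothing to chi2, so dividing by the raw channel count would misstate the
fit quality by roughly 2x.  The divisor used is the *expected* chi-square
of the true model: each channel contributes
`E[(y - mu)^2 / max(y, 1)]` for `y ~ Poisson(mu)` (a tabulated function
of `mu`, ~1 for well-populated channels, peaking near 1.6 around
`mu = 5` and vanishing as `mu -> 0`), with `mu` estimated by smoothing
the observed counts.  From this expectation the fit subtracts the number
of *active* (nonzero) components of the unregularized solution plus one
for the background — the adaptive degrees-of-freedom correction
appropriate to non-negativity-constrained fits, which use only as many
components as the data support (2–3 for a mono-exponential trace, 10–20
for a three-component trace) rather than the full grid size.

### Choice of the regularization weight

`chi2_red(lambda)` is increasing but nearly flat near its noise floor:
between the unregularized minimum and visibly over-smoothed solutions the
reduced chi-square moves by only a few percent, which is comparable to
the accuracy with which the absolute chi-square scale is known.  A hard
absolute target (e.g. "smooth until chi2_red = 1") therefore erases real
structure for the noise realizations whose floor happens to lie low.

The fit instead uses a floor-referenced stopping rule, in the spirit of
noise-level-free parameter-choice methods for ill-posed problems: after
measuring the floor (at `lambda = 1e-4`, within ~0.1% of the non-negative
least-squares minimum but with enough entropy curvature to consolidate
single-channel spikes), `lambda` is raised — decade steps, then log
bisection, each solve restarted from the prior so that components zeroed
at small `lambda` can re-enter — to the *smallest* value whose chi-square
exceeds the floor by a fixed 1% margin, capped at 1.10x the configured
`chi2_target` (default 1.0).  A floor already above that ceiling means
the model cannot represent the data at the declared noise level: the
floor solution is returned with `converged = False` and a warning, never
a silent success.  A stop that lands below the nominal band's lower edge
(0.98x target) is recorded in the diagnostics message.  Typical selected
weights on simulated three-component data are `lambda ~ 1e-3`–`3e-3`.

All-zero traces raise a degenerate-input error; traces with fewer than
1000 total counts are fitted but warn that the inversion is poorly
constrained.

### Verified behavior

On decays simulated at the default acquisition settings from the
three-lifetime landscape (0.40/1.7/5.2 ns at 39/33/28% amplitude), the
inversion resolves three modes and a donor-only mono-exponential gives
one mode in every tested seed; fractional populations come back within
4 points.  Replicate agreement is assessed on a 0.05-dex grid because
~10,000 peak counts localize a sub-ns mode only to a few percent —
comparing peak positions on a finer grid would test the noise, not the
method.  At vanishing regularization the chi-square matches an
independent brute-force weighted-NNLS oracle within 1%, and the modelled
photon flux matches the observed total (minus fitted background) within
2%.

## 3. Gaussian decomposition and FRET

The distribution is decomposed as a sum of Gaussians in log10-lifetime —
the natural domain for a log-spaced grid, where MEM modes are roughly
symmetric.  Candidate models with 1..N components are fitted with lmfit,
centers seeded at smoothed local maxima exceeding 2% of the summed
amplitude, and the count is selected by BIC; N is capped at the number of
resolved maxima (a component per unresolved sub-spike would split one
mode) and at `max_components` (default 4).  Component widths are bounded
to [half a grid step, 0.5 dex]: narrower would fit individual grid
spikes, wider is a baseline absorber rather than a conformational state.
Components holding under 1% of the area are pruned as noise absorbers.
Each component's area over the total is its fractional population
(populations sum to 1 by construction).

FRET efficiencies:

* per peak: `E = 1 - tau_peak / tau_D` with `tau_peak` the component's
  center (peak position), clamped at 0 for reporting when slightly
  negative (a mode at the unquenched donor lifetime can fit marginally
  above `tau_D`); the raw value is kept alongside;
* sample average: `<E> = 1 - <tau_DA> / tau_D` with `<tau_DA>` the
  amplitude-weighted mean lifetime, using either the raw grid amplitudes
  or the Gaussian components.  For a component that is Gaussian in
  log10(tau), the mean lifetime in linear tau is the lognormal mean
  `10^mu * exp((sigma ln 10)^2 / 2)`, not the peak position; using it
  keeps the two `<E>` routes consistent to ~0.02.

`tau_D` is supplied per sample, normally the single peak position of a
donor-only measurement (~4.9 ns for the tricyclic cytosine donor in
duplex DNA).

## 4. Duplex generator and geometry descriptors

### Generator

Idealized duplexes are built from planar base templates: rings as regular
polygons (1.38 Å bonds) with exocyclic substituents placed radially, the
two bases of each Watson–Crick pair docked by a rigid 2-D fit that sets
the donor–acceptor separations to 2.90 Å (three bonds for G:C, two for
A:T).  Pairs are stacked with a fixed rise (3.4 Å) and twist (36°/step)
about the global z axis.  Each nucleotide also carries a pseudo sugar
ring (C1' plus four atoms) hung off C1' away from the base, which gives
the extrusion descriptor its backbone reference points.

Perturbations are rigid rotations applied after assembly:

* *untwist* at a step reduces that step's twist increment;
* a *bend* rotates the entire 3' arm about an axis through the hinge-pair
  origin, perpendicular to the local helix axis, with the bend azimuth
  given in the hinge-pair frame (0° = toward the major groove, 180° =
  toward the minor groove);
* a *base rotation* turns one base about an axis through its sugar-ring
  centroid along the backbone direction from the 3'-neighbor sugar — the
  same axis the extrusion pseudo-dihedral measures about, which is what
  makes that round trip exact.

What the generator does **not** emulate: sequence-dependent step
geometry, propeller/buckle/slide degrees of freedom, backbone torsions
and real sugar puckers, grooves of realistic width, counterions, or
thermal noise.  Descriptor tests passing on these fixtures demonstrate
that the descriptors measure what they claim on controlled geometry; they
do not certify accuracy on distorted experimental structures beyond the
frame conventions shared with standard tools.

### Base-pair frames and twist

Each pair's frame: origin at the C1'–C1' midpoint; y along the
top-to-bottom-strand C1' vector; z the consecutive-origin direction
orthogonalized against y; x = y x z (major groove toward +x, minor
toward −x).  This is a simplified C1'-based convention, not a full
standard-reference-frame fit — self-consistent with the generator and
adequate for twist *differences*, which is what the untwist observable
needs.  Step twist is the signed angle between successive y axes about
the mean local z, in (−180°, 180°]; cumulative twist over a span is the
sum of its steps (exact additivity), and the untwist angle is
`Twist_initial − Twist` per model, positive for unwinding, with
`Twist_initial` supplied by the caller as a number or a reference
sub-ensemble (e.g. the early segment of a trajectory) whose cumulative
twists are averaged.

### Bend angle and bend direction

The bend angle at a hinge is the angle between the principal axes (SVD,
oriented 5'→3') of `arm_length` base-pair origins on either side of the
hinge, excluding the hinge pair itself; a straight helix reads < 0.5°.

The bend-direction pseudo-dihedral is the torsion over four reference
points: the hinge pair's bottom-strand C1' (which anchors the groove
frame through the base-pair long axis), the distal 5'-arm origin, the
hinge origin, and the distal 3'-arm origin.  An earlier candidate using a
minor-groove point displaced along −x as the torsion axis is degenerate
precisely for bends in the minor/major-groove plane (the axis is then
parallel to the bend displacement), so it cannot carry the sign
semantics; the adopted point set keeps the torsion axis along the 5' arm
and the azimuth reference along the base-pair long axis, and its overall
sign is calibrated on generator fixtures so that bending toward the
minor groove is negative and toward the major groove positive —
mirroring the convention used when this observable reports MD ensembles.
Below 2° of bend the azimuth is meaningless and the function returns an
explicit undefined flag (None) instead of a noisy number.

### Base extrusion

The extrusion pseudo-dihedral for a top-strand base is the torsion over
(centroid of the base pair 3' of the site, sugar-ring centroid of the 3'
neighbor, sugar-ring centroid of the flipping nucleotide, base-ring
centroid of the flipping base).  The stacked ideal-duplex value is the
baseline (identical for all interior sites of a homogeneous duplex);
rotating a base out of the stack shifts the dihedral by the rotation
applied (±2° tolerance in tests), sign-symmetrically.

### Hydrogen bonds and block averaging

Hydrogen bonds are detected between tabulated heavy-atom donors and
acceptors of the nucleobases at donor–acceptor distance ≤ 3.5 Å
(D–H...A angle ≥ 120° additionally enforced when explicit hydrogens are
present).  Pairs within a residue or between covalently linked neighbors
(same chain, adjacent residue numbers) are excluded, as in standard
contact analyses.  An ideal G:C pair yields exactly the three
Watson–Crick bonds; an A:T pair two.

Uncertainties of trajectory-style series use block averaging: the series
is cut into `n_blocks` contiguous equal blocks (trailing remainder
discarded), and the standard deviation of block means estimates the
error of the mean in the presence of autocorrelation; for iid data it
reproduces sigma/sqrt(L) (L the block length), for positively correlated
series it is larger, and a scan over block counts (`block_scan`) exposes
the plateau.

### Missing atoms

Experimental structures of open protein–DNA complexes commonly leave the
flipped-out nucleotides unresolved.  Descriptors that need absent atoms
raise a `MissingAtomsError` naming every missing atom
(`chain:resid:name`) rather than silently skipping pairs, so ensembles
with gaps fail loudly per descriptor.

## 5. Pipeline and reproducibility

`run_pipeline` executes simulate (or read) → MEM → peak decomposition →
FRET, plus the geometry stage when a structure is configured, from a
single flat YAML config validated up front against each stage's
preconditions.  All randomness flows from the configured seed; outputs
(distribution TSV, landscape TSV, JSON summary, descriptor TSV) embed
the tool version and a hash of the scientific settings, and a rerun with
the same config is byte-identical.  Stage failures abort with the stage
name and cause.

## 6. Problem sizes used in the test and acceptance runs

Decay analyses run at the full default acquisition (4096 channels,
10,000 peak counts); the seed studies use 10 seeds per sample.  The
NNLS-oracle cross-check uses 512 channels and a 32-point grid, where the
brute-force oracle is exact and fast.  Geometry tests use 24-bp
duplexes (1–20 models) and 10,000-point series for block-averaging
statistics.

## 7. Known limitations

* The entropy prior, grid, and stopping rule of the original MEM software
  this emulates are not published; the choices here are declared above
  and are not claimed to be identical.
* Gaussian areas on sharply peaked (near-floor) MEM solutions carry a
  few-percent allocation bias between overlapping modes; populations are
  quoted with that in mind.
* The geometry descriptors use simplified C1'-based frames; absolute
  twist values differ from full standard-reference-frame fits by a
  sequence-dependent offset, which cancels in the untwist difference.
* The generator's bases are idealized planar templates; hydrogen-bond
  geometry is exact by construction, not representative of thermal
  ensembles.
* No acceptor photophysics, bleaching, anisotropy, or pile-up effects in
  the decay model, and no stretched-exponential or global multi-trace
  fitting in the inversion.
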