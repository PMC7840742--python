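# Methods

This note records the models implemented in `memperm`, the numerical
choices behind them, and what the synthetic-data tests do and do not
demonstrate about real membrane simulations.

## Solubility–diffusion permeability

Passive permeation is treated as partitioning into the bilayer, diffusion
across it, and partitioning out the far side.  With a free-energy profile
*w(z)* (kcal/mol) and local diffusivity *D(z)* (Å²/ps) along the membrane
normal, the permeability is

    1/P = R = ∫_{z1}^{z2} exp(β w(z)) / D(z) dz,   β = 1/(k_B T),

with k_B = 1.987204259·10⁻³ kcal/(mol·K) and T defaulting to 310 K (the
fluid-phase regime of a POPC/cholesterol bilayer).  R carries ps/Å so
P = 1/R is Å/ps; 1 Å/ps = 10⁴ cm/s.

The integral is evaluated by the trapezoid rule on the PMF bin grid
restricted to [z1, z2], with the exact endpoints added by linear
interpolation.  For a constant integrand the trapezoid rule is exact, so
the flat-landscape closed form P = D₀/L holds to machine precision.

**Gauge.**  exp(βw) is not gauge invariant: w must be anchored so the
bulk-water plateau is the zero of energy.  `wham(anchor=...)` offers
"min", "bulk" (mean of the outermost three bins on each side),
"bulk-upper" (one-sided profiles) and "none".  Permeability integrals
should use a bulk anchor.

## Umbrella sampling and WHAM

Windows are harmonic restraints U = k(z−z₀)² at a ladder of centers.  The
`k`-prefactor convention (no ½) is the default because it matches the
restraint form of the MD engines whose spring constants (1.5–3.0
kcal/mol/Å²) these analyses typically consume; a per-window flag switches
to ½k.  Getting this wrong silently halves or doubles the effective
stiffness, which is why it is explicit rather than assumed.

`wham` solves the standard self-consistent equations on a z-histogram:

    P(z_b) ∝ Σ_i n_i(z_b) / Σ_i N_i exp(β(F_i − U_i(z_b)))
    exp(−βF_i) = Σ_b P(z_b) exp(−βU_i(z_b))

iterated until max|ΔF_i| ≤ tolerance (10⁻⁷ kcal/mol default), then
w(z_b) = −k_BT ln P(z_b).  Interior bins visited by no window indicate a
sampling gap between adjacent windows and raise an error rather than
silently bridging.  A binned estimator targets the *bin-averaged*
Boltzmann weight, so recovery tests compare against
−k_BT ln⟨e^{−βw}⟩_bin, not the center-point value — the distinction
matters only where w is steep (several kcal/mol per bin at domain edges).

**Errors.**  Bootstrap errors redraw each window's histogram from a
multinomial with an effective sample size N_i/g_i, where the statistical
inefficiency g_i = 1 + 2τ_int comes from the window series'
autocorrelation.  Deviations of adjacent bins are strongly correlated
(window free-energy offsets perform a random walk along the ladder), so
error bands should be read curve-wise, not bin-wise.

**Symmetrization.**  A bilayer is symmetric about its midplane;
`symmetrize` reflects a one-sided profile across z = 0 (values become an
even function), and `reflect_windows` mirrors the window *data* before
WHAM, duplicating the z = 0 window or not as requested.  An
already-symmetric profile passes through unchanged; a two-sided
asymmetric one is rejected.

**Window count bookkeeping.**  A 1 Å ladder from z_top = 38 to the
midplane inclusive has 39 centers; dropping the midplane endpoint gives
38.  `make_window_centers` exposes the choice and the count is always
explicit — off-by-one window bookkeeping is a classic silent error in
reflected-profile WHAM.

## Position-dependent diffusion

Each window's restrained z series gives a local diffusion coefficient via
the positional-autocorrelation estimator

    D = var(z)² / ∫₀^{T*} C(t) dt,    C(t) = ⟨δz(0) δz(t)⟩,

which is exact for an Ornstein–Uhlenbeck process (D = var/τ).  The
autocovariance is computed by FFT with the biased (1/n) normalization and
integrated by a left-Riemann sum, so a white-noise series yields
∫C dt = var·Δt and D = var/Δt — the correct discrete-time limit.

**Truncation T\*.**  The default is automatic windowing: truncate at the
smallest lag k with k·Δt ≥ 5 × the running correlation-time estimate
I(k)/C(0).  Truncating at the first zero crossing of C is also available
("first-zero", with a single-exponential tail fit when C never crosses
zero), but its crossing point drifts to larger lags as the series grows,
accumulating tail noise — in end-to-end tests the first-zero estimator's
error did not shrink with sampling, while the windowed estimator's does.
The rule used is recorded per window.

Diagnostics per window: variance, correlation time, truncation method,
and a normalized linear-drift statistic (|slope|·T/σ_z) flagging grossly
non-stationary series.  Windows whose restraint straddles a reflecting
domain boundary (the outermost windows of a synthetic set) carry a known
low bias in D — their distribution is truncated — but contribute little
to the permeability integral, which is dominated by the barrier top.

The profile D(z) is assembled by sorting windows by their mean position
and interpolating piecewise-linearly; beyond the outermost window means
the end value is held flat and the extrapolated points are flagged.

## Membrane structure descriptors

* **APL** = Lx·Ly/N per frame, N the phospholipids per leaflet.
  Cholesterol is *not* counted in N — the phospholipid-count convention —
  and the choice is the caller's, surfaced as an explicit argument.
* **EDP**: each atom deposits Z − q electrons (atomic number minus
  partial charge) in the bin containing its z; per-frame histograms are
  divided by the instantaneous bin volume Lx·Ly·Δz and averaged.  Bin
  width defaults to 1 Å over the full box z-extent.  Symmetrization about
  z = 0 is an explicit flag, off by default: an equilibrated bilayer
  should come out symmetric on its own, and forcing symmetry can mask
  drift.  The profile conserves electrons: Σ values·Lx·Ly·Δz equals the
  selection's total electron count up to the reported out-of-range tally.
* **S_CD** = ⟨½(3cos²θ − 1)⟩ over C–H bond orientations versus the
  normal, averaged over hydrogens, lipids and frames per carbon position.
  Both the signed average and its magnitude are reported; NMR-style plots
  conventionally show the magnitude (~0.2 near the headgroup).
  Inequivalent hydrogens at carbon 2 are averaged into their position,
  matching the single-curve-per-chain presentation.
* **Leaflets**: a lipid is upper/lower by the sign of its phosphate z in
  a recentered frame; z = 0 goes upper with a warning.

Partial charges ride in a two-column sidecar table because the PDB format
cannot carry them portably; missing charges default to zero with a
warning (this biases the EDP by the net partial charge, which is zero for
neutral systems).

## Statistical geometry

Selected heavy atoms (lipid phosphates, sterol and water oxygens) are
Delaunay-tessellated per frame with scipy's Qhull wrapper.  Lateral
periodicity is handled by adding ghost images within a 15 Å margin in x
and y (beyond any nearest-neighbor spacing of interest), discarding
simplices with no primary vertex, and de-duplicating by primary-index
set; z is non-periodic (bulk water bounds the membrane).  Near-degenerate
slivers (volume below 10⁻⁹ × edge³) are filtered with a warning.

Each tetrahedron's distortion is

    T = Σ_{i<j} (l_i − l_j)² / (15 l̄²)

over the 15 unordered pairs of its 6 edge lengths.  T = 0 iff all edges
are equal, and T is invariant under rotation, translation and uniform
scaling.  The denominator reads l̄² as (mean edge length)² — the standard
statistical-geometry convention; the mean-of-squared-lengths variant is
available (`mean_square=True`) since the printed formula is ambiguous
between the two, and both vanish for regular tetrahedra.  Distributions
are pooled across frames (a per-snapshot geometric statistic needs no
temporal smoothing); the histogram is normalized as a density
(Σ p·ΔT = 1) and summarized by mode, mean and tail fraction.

## Permeant interactions

* **Tilt**: angle of the tail→head atom vector versus +z, in [0°, 180°].
* **Insertion depth**: reported under *two* conventions — distance of the
  permeant COM z to the nearest leaflet's mean phosphate z (plane
  convention) and the minimum 3-D COM-to-phosphate distance — because
  "distance from the phosphate atoms" is convention-dependent and a
  mean ± sd pair near 30 ± 8 Å is consistent with more than one reading.
  Neither is asserted as canonical.
* **Hydration shell**: water oxygens within 3.5 Å (the conventional first
  shell), minimum-image in x, y; summaries are pooled over frames ×
  atoms.
* **H-bonds**: present iff d(D,A) ≤ 3.5 Å and the D–H⋯A angle ≥ 135°
  (gap tolerance 0).  No universal printed criterion exists for lifetime
  tables, so the defaults follow common practice and are exposed;
  lifetime results should be quoted with their criterion.  Lifetimes are
  contiguous-run lengths × frame interval, with runs bridged across gaps
  ≤ tolerance counting the gap toward the lifetime; the per-oxygen
  "maximum lifetime" is the longest run over all pairs sharing that
  acceptor.  Run/gap bookkeeping conserves frames.
* **RDF**: g(r) = ⟨pairs in [r, r+dr)⟩/(N_a ρ_b 4πr²dr), minimum-image
  in x, y.  ρ_b defaults to the b-selection's occupied z-slab rather than
  the whole box: selections confined to planes (phosphate atoms) would
  otherwise depress g systematically.  Whole-box density is a switch.
  Because z is non-periodic, the plateau of a truly homogeneous system
  shows a slab-edge deficiency of order r/L_z — negligible for tall
  boxes.
* **Native contacts**: heavy-atom pairs within 4.5 Å in a reference frame
  (defaulting to the first frame with the permeant COM below the
  phosphate plane, i.e. membrane entry); Q(t) is the retained fraction,
  reported separately per partner region (head vs tail) so interaction
  preferences are visible.  Zero reference contacts yield an explicit
  absent result, not Q = 0.

## Synthetic generators

The Langevin simulator integrates the Itô–Euler update

    z ← z + [−βD(z)(w′ + U′) + D′(z)]·dt + √(2D(z)dt)·ξ

with reflecting boundaries.  The spurious-drift term D′(z) is included so
the stationary law is exactly ∝ e^{−β(w+U)} for *any* positive D(z);
omitting it would skew the law by 1/D(z) and WHAM-recovery tests would
conflate estimator error with generator bias (a test verifies the uniform
law survives a strongly modulated D).  Free diffusion on a flat landscape
takes an exact vectorized path (partial sums of Gaussian steps folded at
the boundaries).

Defaults are desk-scale by design: 10⁴–10⁶ steps per window, ≤ 20 lipids
per leaflet, ≤ 500 waters, chosen so the full pipeline and its tests
complete in minutes on one CPU while leaving every estimator in its
asymptotic regime.  dt is checked against the deterministic step length
(warning if max|βDw′|dt exceeds a tenth of the domain).

The bead bilayer is *not* chemically realistic: heads are single N/P
beads on a lattice at ±head_z, chains are straight bead strings at a
prescribed tilt with one hydrogen per carbon laid along the chain axis
(so fixed tilt θ gives S_CD = ½(3cos²θ−1) exactly at every position),
charges come from a fixed internal table, and waters are single oxygens
uniform outside the slab.  The box dimensions of real systems are not
prescribed anywhere authoritative; fixtures choose 24–25 Å lateral boxes
and 60 Å height and record them in the ground-truth dictionary.

Telegraph series discretize alternating exponential dwells at the frame
interval; the generator records the continuous dwells it drew, which is
the unbiased oracle for lifetime estimators (discretization drops
sub-frame dwells and merges runs across unsampled gaps — an O(dt/mean)
effect that the tests keep below their statistical resolution by using
dt ≪ mean dwell).  OU series use the exact discrete recursion
z' = z·e^{−dt/τ} + √(var(1−e^{−2dt/τ}))·ξ from a stationary start.

All generators are pure functions of (spec, seed); re-runs are
byte-identical, and umbrella-set window seeds derive deterministically
from (seed, window index).

## What the tests show — and what they don't

Passing recovery tests on synthetic data demonstrates that the
*estimators* are correct and internally consistent: WHAM inverts exactly
Boltzmann-distributed biased samples, the diffusion estimator matches the
OU closed form, and the assembled pipeline reproduces a prescribed
permeability within its sampling error (factor ≲ 1.5 at the default
budget, shrinking with sampling).  They do not validate force fields,
equilibration of real bilayers, the 1-D projection of an inherently 3-D
permeation process, or the Markovian assumption behind the
solubility–diffusion model — those are properties of the data, not of
this code.

## Known limitations

* WHAM only (no MBAR), 1-D reaction coordinates only.
* Orthorhombic boxes; lateral (x, y) periodicity only — z-profiles assume
  the membrane sits inside the box with bulk water at the edges.
* The H-bond lifetime is the run-length ("intermittent off" only via the
  gap tolerance); no Luzar–Chandler correlation-function kinetics.
* Diffusion estimates in windows clipped by a reflecting boundary are
  biased low; flat extrapolation of D beyond the outermost windows is
  flagged but still an approximation.
* The synthetic bilayer tests geometry and bookkeeping, not chemistry.
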