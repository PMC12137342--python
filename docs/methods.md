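# Methods

## Decay data and chain physics

Half-lives, branching fractions and mean energies per decay (MeV, pooled into
alpha / electron / photon classes) live in `src/rptdose/data/nuclides.yaml`,
a versioned, human-readable file in the style of evaluated decay-data
compilations. The file — not the code — is the source of truth; swapping it
changes data versions without touching the solver. Only mean energy per decay
is modeled, not line spectra: for self-dosing-sphere dosimetry with full
charged-particle absorption, the mean is all that enters.

Chain activities for a pure parent at t = 0 use the analytic Bateman solution
generalized to branching: the activity of member *n* is the sum over all
root→n decay paths of the classic product-form solution weighted by the
path's branching product. Two numerical decisions matter:

- **Extended precision.** The ²²⁵Ac series spans ~11 orders of magnitude in
  decay constant (²¹³Po at 4.2 µs vs the 9.92 d parent). The alternating
  product-form terms then cancel catastrophically at times where a late
  member's activity is still building up (relative error ~3×10⁻⁵ in double
  precision at t = 1 s for ²⁰⁹Pb). Coefficients and exponential sums are
  evaluated in 80-bit long doubles, which brings agreement with a stiff ODE
  (Radau) reference below 10⁻⁸ relative everywhere from 1 s to 30 d.
- **Degenerate decay constants.** Near-equal λ pairs (relative difference
  < 10⁻¹²) would hit the removable singularity of the product form; they are
  perturbed by 10⁻⁹ relative with a warning. The induced error is far below
  any physical uncertainty in the data.

Cumulated decays per parent decay default to the branching-product
(equilibrium) bookkeeping: every ²²⁵Ac daughter has T½ ≤ 3.3 h against a
~10 d parent, daughters are assumed to decay where the parent decayed (no
redistribution), so each parent decay is eventually matched by the
branching-weighted decays of every descendant. The Bateman-integral mode
exists as a cross-check and agrees to ~10⁻¹⁶. Very short-lived members
(²¹⁷At, ²¹³Po) are kept as explicit chain members so the per-nuclide energy
bookkeeping stays auditable. ²⁰⁹Pb (β, 3.25 h) is included as a dose
contributor like every other radioactive member.

`equilibrium_fraction` models the counting protocol for ²²⁵Ac samples, which
are held overnight so ²¹³Bi grows into secular equilibrium before gamma
counting: after 12 h the ²¹³Bi activity is within 2×10⁻⁵ of its equilibrium
ratio. Input %IA/g is interpreted as parent concentration with that
equilibration already folded in by the experimenters; the function is offered
as a QC/correction utility and no rescaling is applied by default.

## Biodistribution bookkeeping

%IA/g is referenced to the injection time: decay correction multiplies a
measured activity by 2^(elapsed/T½), and %IA/g = 100·activity/(injected ×
mass). Files are plain CSV (header `animal_id,organ,time_h,pct_ia_per_g,
organ_mass_g[,body_mass_g]`, times in hours, `# key: value` comment lines as
metadata); internally everything is SI. Organs may be missing at some time
points; integration uses whatever points exist and errors below two. The
caliper tumor volume uses the ellipsoid convention (π/6)·L·W·H; the ½·L·W²
spheroid shortcut is common in the field, so every report stamps which
convention produced its numbers.

## Time-integrated activity

The integrand is the *physical* activity concentration per unit injected
activity — `build_tac` multiplies decay-corrected %IA/g back by 2^(−t/T½) —
so the trapezoid body and the analytic tail describe the same decaying
quantity. The tail beyond the last sample assumes pure physical decay of the
administered parent (no biological clearance), and the default rise model
runs linearly from (0, 0) to the first sample, since an IV-injected agent
starts at zero tissue concentration; a `flat` option (hold conc(t₁) back to
t = 0) exists because the choice is a convention. Aggregation defaults to the
group mean across animals at each time point (the n = 3 design); per-animal
curves are available to propagate variance. No curve fitting is used on the
integration path — trapezoids are the method being implemented; biexponential
kinetics exist only in the generator.

Two systematic biases of this estimator are worth knowing: trapezoids
over-estimate convex decaying segments on coarse grids, and the
physical-decay tail over-estimates whenever real biological clearance
continues past the last sample (by the factor (k_clear+λ)/λ on the tail
portion). Both push doses up — conservative for normal-tissue assessment.

## Sphere dosimetry

Charged-particle absorbed fraction is 1 at organ scale (mm-range betas,
µm-range alphas); the photon absorbed fraction is selectable: `escape`
(φ = 0, default — mouse organs are small and photon self-dose is a percent-
level term), `local` (φ = 1, an upper bound useful for energy-conservation
checks), or `table` (a packaged, synthetic mean-chord-attenuation
approximation, interpolated in log mass, covering 0.05–10 g). Organ masses
are allometrically scaled, mass = reference × (body/25 g)^exponent with
exponent 1.0 by default (per-organ overrides supported); tumors always use
their measured mass (or caliper volume × 1 g/cm³). RBE = 1 throughout —
doses are physical absorbed doses, and any alpha-weighting is left to the
reader. Doses are reported to 3 decimals in tables. Every `DoseResult`
carries its conventions (rise, tail, aggregation, photon model, daughter
mode) so numbers are traceable to choices.

Note that with φ = 1 charged particles and escaping photons, the organ mass
algebraically cancels between cumulated decays (per gram × mass) and the
sphere factor (energy / mass); it re-enters only through the photon table.

## Synthetic studies and what they do (not) show

The generator emulates the study design the pipeline targets: sampling at
4, 24, 72, 120, 192 h with 3 animals per point; biexponential organ kinetics
b(t) = A·(e^(−k_c t) − e^(−k_u t)) peaking at ln(k_u/k_c)/(k_u−k_c);
multiplicative unit-mean lognormal noise per animal×organ×time with CV 0.2
by default (concentrations are positive and right-skewed; the true
inter-animal CV of such studies is not well pinned down and 0.2 is a
documented placeholder). A mandatory seed drives a named generator
(`numpy.random.default_rng`) and is recorded in the output metadata.

Four presets (TRAMP-C1 / Myc-CaP × ¹⁷⁷Lu / ²²⁵Ac) are labeled synthetic and
qualitatively reproduce the kinetics such studies describe: tumor %IA/g
peaking at the 24 h sample with retention through 72 h; liver peaking early
(24 h) for ¹⁷⁷Lu but accumulating late (120–192 h) for ²²⁵Ac; hepatobiliary-
dominant normal-tissue uptake; fast-clearing blood. Biological clearance
rates in the presets are slow relative to physical decay (k_clear ≤
~0.001 h⁻¹ for retained organs) — consistent with the prolonged retention of
phospholipid-ether agents, and a precondition for the physical-decay tail to
be a small bias (see above). Amplitudes were chosen to give tumor and liver
doses of the same order as published preclinical values for this agent class
(single-digit to tens of Gy at MBq/kBq-scale injected activities); they are
not fits to any measured dataset.

Because the generator's truth is a biexponential with exactly the noise
model the pipeline assumes, passing recovery tests demonstrates correctness
of the integration/dose algebra and robustness to sampling and lognormal
noise — not fidelity to real pharmacokinetics (multi-compartment washout,
daughter redistribution in vivo, inter-organ correlation are all absent).

`true_dose` pushes the closed-form integral A·(1/(k_c+λ) − 1/(k_u+λ))
through the same dose-factor algebra as the pipeline, giving an exact oracle.
Recovery on the 5-point design is within 10% for every preset organ
(dominated by the tail and trapezoid biases above); a dense 50-point
geometric design over [1 h, 12·T½] shrinks it below 1%, and the median
pipeline/truth ratio over 200 noisy studies stays within [0.9, 1.15].
Problem sizes in the acceptance script (20 oracle times, 200 seeds, 50-point
dense design) were chosen so the full run completes in seconds while leaving
the comparisons well-resolved.

## TME metrics

Fold changes compare stratum means (not medians) and are computed per day;
log2FC is evaluated as log2(mean_treated) − log2(mean_control), which makes
the control-vs-itself identity exactly 0 and the treated/control swap exactly
antisymmetric in floating point. Control reference bands use the
t-distribution CI of the control mean. Per-animal CD8/Treg ratios with a zero
Treg denominator are flagged infinite and excluded from the stratum mean with
a warning. Hypothesis testing (ANOVA, t-tests) is routine statistics and out
of scope.

## Known limitations

- No in vivo daughter redistribution or recoil pharmacokinetics: ²²⁵Ac
  daughter energy is deposited where the parent decayed. Late liver
  accumulation of recoiling daughters is a real phenomenon this model cannot
  represent.
- No cross-organ photon dose or voxel-level transport; the sphere model
  ignores organ geometry entirely.
- The trapezoid/physical-tail estimator is biased high for organs with
  substantial ongoing biological clearance at the last time point.
- Decay data are rounded compilation-style values; swap the data file for
  evaluated data if decay-data fidelity matters downstream.
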