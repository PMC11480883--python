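# Methods

## Model

Backbone amide ¹⁵N relaxation is driven by reorientation of the N–H
bond vector.  Its second-order orientational correlation function is
modelled as a normalized multi-exponential,
g(t) = Σᵢ αᵢ e^(−t/τᵢ) with Σαᵢ = 1, giving the spectral density

    J(ω) = Σᵢ αᵢ · 2τᵢ / (1 + ω²τᵢ²),   J(0) = 2·τ_eff,
    τ_eff = Σᵢ αᵢτᵢ  (the area under g).

Two relaxation mechanisms are included: the ¹H–¹⁵N dipolar coupling
(one amide proton, N_H = 1) and an axially symmetric ¹⁵N chemical
shift anisotropy.  With d the dipolar coupling constant, the Redfield
rates are

    R₁  = (d²/40)[J(ωH−ωN) + 3J(ωN) + 6J(ωH+ωN)] + (Δσ²ωN²/15)·J(ωN)
    R₂° = (d²/40)[4J(0) + J(ωH−ωN) + 3J(ωN) + 6J(ωH) + 6J(ωH+ωN)]
          + (Δσ²ωN²/90)[4J(0) + 3J(ωN)]
    NOE = 1 + (γH/γN)(d²/40)[6J(ωH+ωN) − J(ωH−ωN)]/R₁.

These prefactor conventions are fixed jointly by the J(0) = 2τ_eff
normalization and by the requirement that the derived proportionality
constants k = (4K1+4K2)⁻¹ (K1 = d²/20, K2 = Δσ²ωN²/45) reproduce the
published per-field values at 300–1500 MHz to their printed two
decimals; the extreme-narrowing NOE limit 1 + ½γH/γN and a
Fourier-quadrature oracle for J(ω) independently confirm the R₁/NOE
side.  R₂° denotes the transverse rate *without* chemical exchange:
R₂° = R₂ − R_ex.

## Constants

| quantity | value | note |
|---|---|---|
| γH | 2.6752218744×10⁸ rad s⁻¹ T⁻¹ | CODATA |
| γN | −2.7126180436×10⁷ rad s⁻¹ T⁻¹ | CODATA; sign enters only the NOE |
| ℏ  | 1.054571817×10⁻³⁴ J s | CODATA |
| Δσ | −160 ppm | ¹⁵N CSA, axially symmetric |
| r_NH | 1.01 Å | effective bond length; d uses ⟨r³⟩ = r_NH³ |

All internal quantities are SI (rad/s, s, s⁻¹); ns and MHz appear only
at I/O boundaries.  Magnetic fields are specified as the proton Larmor
frequency in MHz throughout.

## Estimators

**Linear.**  τ_eff = k·R₂°.  Because the Lorentzian terms in the R₂°
decomposition are non-negative, this is an exact upper bound for any
timescale distribution; it overestimates τ_eff materially only below
~3 ns (≈34% at 3 ns and 600 MHz, <0.3% at 50 ns).  Error propagation:
στ = k·σR₂.

**Fitted line.**  τ_eff[ns] = m·R₂° + c with per-field (m, c)
calibrated against MD simulation data, tabulated at 15 fields
(300–1500 MHz).  The lines are *not* interpolated between fields — the
calibration is per-field and interpolation would be unvalidated.  A
non-positive result (possible at small R₂ since c < 0) is returned
flagged as non-physical, never clamped.

**One-timescale inversion.**  The unique τ with
R₂°(single-timescale τ) = R₂, found by Brent root search on
τ ∈ [10⁻¹³, 10⁻⁶] s (R₂°(τ) is strictly increasing there; xtol 10⁻²⁰,
rtol 10⁻¹⁵, round-trip error ≲10⁻¹⁰ relative).  An R₂ outside the
achievable interval raises an error reporting that interval.  This
estimator is the lower limit of τ_eff for fast residues and converges
to the linear estimator above (difference <2% at 50 ns).

**Feasible bounds.**  Both R₂° and τ_eff are linear in the mixture
weights, so the set of (R₂°, τ_eff) pairs attainable by any
multi-exponential model is the convex hull of the single-timescale
curve.  The upper boundary is exactly k·R₂°; the lower boundary is
computed as the lower convex hull of the curve sampled on a
log-spaced grid (default 2000 points over 10⁻¹³–10⁻⁶ s).  Chords
between grid points sit marginally above the continuous boundary;
with the default grid the bound is accurate to ~10⁻⁵ relative, and
containment tests allow 10⁻⁴ slack for this discretization.

**Chemical-exchange correction.**  Exchange on µs–ms timescales adds
R_ex to the measured R₂.  In the fast-exchange limit R_ex scales with
the square of the field, modelled here as R_ex = Φ·ωN² with a single
amplitude Φ ≥ 0 per residue.  Given R₂ at ≥2 distinct fields (distinct
meaning >0.5 MHz apart), the solver minimizes
Σ_fields [R₂ − R₂°(τ) − Φ·ωN²]² over (log τ, Φ) with a
single-timescale forward model, internally parametrized by R_ex at
the lowest input field so both parameters are O(1) (trust-region
least squares, bounded).  If the unconstrained optimum would need
Φ < 0, Φ is pinned to zero and the estimate flagged.  The ωN² scaling
law is an assumption of this package: it is the standard fast-exchange
form and the only field-scaling consistent with making τ_eff
field-independent after correction; B₀² scaling is identical up to a
constant absorbed in Φ.

Estimator precision under noise, measured by simulation: with τ = 5 ns,
R_ex(500 MHz) = 2 s⁻¹ and 2% Gaussian noise on R₂, the median τ error
is ~3.7% using four fields (400/500/600/700 MHz) and ~6% using only
500/600/700 MHz — closely spaced high fields poorly separate the
τ-driven and ωN²-scaled parts of R₂, so spreading the fields matters
more than adding precision at one of them.

## Correlation toolkit

**ACF estimator.**  g(Δ) = ⟨P₂(u(t)·u(t+Δ))⟩ over all time origins,
P₂(x) = (3x²−1)/2, computed with FFT cross-correlations of the six
unique component products u_a·u_b (O(N log N)).  Lag 0 is exact (unit
norms) and is used to *verify* normalization, never to renormalize
silently.

**Rotational diffusion generator.**  Unit-vector random walk: each
step applies a rotation with independent Gaussian angular
displacements of variance 2·D_r·dt per axis (valid for D_r·dt < 0.05),
giving g(t) = exp(−6·D_r·t) in expectation.  It is the synthetic
stand-in for MD-derived N–H vectors: it reproduces single-exponential
orientational decorrelation with a known answer, but none of the real
features of protein N–H motion — no sub-ns librational component, no
separation of internal and overall motion, no anisotropy.  Passing
tests therefore validate the estimator chain, not any biological
claim.

**Multi-exponential fit.**  Non-negative least squares for the weights
on a fixed log-spaced timescale grid (64 points from 1 ps up to the
last observed lag, hard-capped at 1 µs) — convex, reproducible, no
initialization sensitivity.  The grid is capped at the observation
window because longer timescales are not identifiable from the data;
on Monte-Carlo-noisy ACFs an uncapped grid soaks up tail noise into
µs components and inflates τ_eff severely.  Individual (αᵢ, τᵢ) are
generally not identifiable; τ_eff is, and tests assert only τ_eff.
Weight concentrating (>50%) on the longest grid timescale flags the
fit as non-decaying.

**τ_eff by integration.**  Trapezoidal area under g plus a tail
correction: an exponential fitted to the last decade of lags is
integrated to infinity (default), or the tail is taken as zero
(`truncate`, which biases τ_eff low by the remaining tail mass).
Non-decaying input yields a flagged estimate.

## Pipeline sizes used in tests and the acceptance script

Stochastic checks use a D_r = 5×10⁷ s⁻¹ trajectory with dt = 50 ps and
10⁶ frames (50 µs, ≈15,000 correlation times) and an ACF lag window of
1000 frames (50 ns ≈ 15 decay times): long enough that the
Monte-Carlo error of the recovered τ_eff (~2–5% across seeds) sits
well inside the 10% closure check, while keeping the whole pipeline
under ~10 s.  The exchange-recovery simulation uses 200 replicates.

## I/O conventions and policies

- CSV/TSV columns: `residue,resname,field_MHz,R2,R2_err,R1,hetNOE,region`;
  a `column_map` renames, a `field_mhz` argument (CLI `--field`)
  supplies a missing field column.
- NMR-STAR 3.1: heteronuclear T₂/R₂ save-frames are located by
  category or `_T2.*` loop tags; stored T₂ (s or ms, per
  `T2_val_units`) is converted to R₂ = 1/T₂ with first-order error
  propagation.  The reader is a minimal purpose-built STAR parser
  covering save-frames, loops, quoted and semicolon-delimited values.
- Records within 0.5 MHz are treated as the same field.
- Missing or non-positive R₂/T₂ rows are skipped with a logged
  warning and counted — never imputed.
- Input R₂ is treated as R₂° by single-field estimators.  When the
  exchange contribution is unknown this overestimates τ_eff for
  affected residues (qualitatively the right direction — exchange
  does indicate slower effective dynamics — but quantitatively
  unreliable); the multi-field `rex-corrected` estimator is the
  remedy.
- τ_eff is reported in ns to 2 decimals by default (`--precision
  full` for full precision); flagged estimates keep their raw value
  plus the flag so downstream tables can show "missing, reason".

## Known limitations

- Isotropic overall motion is implicit in the one-timescale inversion;
  anisotropic diffusion tensors are out of scope.
- The fitted (m, c) lines exist only at the 15 tabulated fields.
- The exchange model assumes fast exchange at every field; slow or
  intermediate exchange breaks the ωN² scaling and will surface as a
  poor multi-field fit rather than being detected explicitly.
- The feasible lower bound is a numerical hull, exact only up to grid
  discretization (~10⁻⁵ relative at defaults).
- Region labels (folded/disordered) are user input; the package does
  not assign secondary structure.
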