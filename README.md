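# taueff

Effective rotational correlation times of protein backbone N–H bonds,
directly from transverse ¹⁵N spin relaxation rates.

## The problem

NMR spin relaxation (R₁, R₂, hetNOE of backbone ¹⁵N) is the workhorse
probe of per-residue protein dynamics, but interpreting it is hard for
intrinsically disordered proteins (IDPs), multidomain proteins and
peptides in micelles, whose motions span many timescales and defeat
few-parameter models such as the Lipari–Szabo decomposition.  A robust,
intuitive alternative is the **total effective correlation time**

τ_eff = Σᵢ αᵢτᵢ — the area under the normalized second-order
orientational correlation function g(t) = Σᵢ αᵢ e^(−t/τᵢ) of the N–H
bond, containing internal *and* overall rotations.

Substituting the multi-exponential spectral density
J(ω) = Σᵢ αᵢ·2τᵢ/(1+ω²τᵢ²) (so J(0) = 2τ_eff) into the Redfield
expression for the exchange-free transverse rate R₂° splits it into a
term linear in τ_eff plus four non-negative Lorentzian terms:

```
R₂° = (4K1 + 4K2)·τ_eff + Lorentzian terms,
K1 = d²/20 (¹H–¹⁵N dipolar),  K2 = Δσ²ωN²/45 (¹⁵N CSA)
```

so that

```
τ_eff = k·R₂°,    k = (4K1 + 4K2)⁻¹
```

is an exact **upper bound** on τ_eff for any timescale distribution and
an excellent approximation for residues slower than ~3 ns.  `taueff`
implements this linear estimator, a per-field MD-calibrated correction
line τ_eff = m·R₂° + c, a numerically inverted one-timescale Redfield
model (the lower limit for fast residues), feasible-region bounds over
all timescale mixtures, and a multi-field chemical-exchange correction
(R_ex = Φ·ωN², fast exchange), plus the forward Redfield calculators
and a correlation-function toolkit for trajectory-derived N–H vectors.

Who it is for: NMR spectroscopists and simulators who have per-residue
R₂ values (one field suffices) and want field-independent, intuitively
interpretable rotational timescales without model-free fitting or MD.

## Worked example

Proportionality constants and a single-residue estimate:

```
$ taueff ktable --field 500
field_MHz,k_1e-9_s2
500.0,0.75

$ taueff tau linear --field 600 --r2 10
residue,resname,field_MHz,R2,tau_eff_ns,tau_err_ns,rex_s,estimator,flag,region
1,,600.0,10.0,6.96,,,linear,,
```

At 600 MHz, k = 0.70×10⁻⁹ s², so R₂° = 10 s⁻¹ means the N–H bond of
this residue rotates with a total effective correlation time of at
most 6.96 ns; the MD-calibrated line (`taueff tau fitted …`) gives
6.46 ns and the one-timescale inversion (`taueff tau onets …`)
6.24 ns.  The estimators bracket a ~10% window because ~6 ns sits
near the edge of the strictly linear regime.

The same from Python, with the feasible range over all timescale
mixtures:

```python
>>> import taueff
>>> f = taueff.make_field(600)
>>> est = taueff.tau_eff_one_timescale(10.0, f)
>>> round(est.tau_eff * 1e9, 2)
6.24
>>> lo, up = taueff.feasible_tau_bounds(10.0, f)
>>> round(lo * 1e9, 2), round(up * 1e9, 2)
(5.92, 6.96)
```

A full trajectory pipeline — simulate isotropic rotational diffusion
(D_r = 5×10⁷ s⁻¹, so the true decay time is 1/(6·D_r) = 3.33 ns),
estimate the P₂ autocorrelation, fit a multi-exponential model,
compute R₂ and invert:

```python
>>> traj = taueff.simulate_rotational_diffusion(5e7, 5e-11, 1_000_000, seed=1)
>>> g = taueff.p2_autocorrelation(traj, 1000)
>>> model = taueff.fit_multiexponential(g).model
>>> r2 = taueff.relaxation_rates(model, f).r2
>>> round(taueff.tau_eff_one_timescale(r2, f).tau_eff * 1e9, 2)
3.27
```

Experimental tables are read from CSV/TSV
(columns `residue,resname,field_MHz,R2,R2_err,R1,hetNOE,region`) or
NMR-STAR 3.1 heteronuclear T₂/R₂ save-frames (`--star`); T₂ values are
converted to R₂ = 1/T₂.  Note that single-field estimators treat the
input R₂ as exchange-free R₂° — when a chemical-exchange contribution
is suspected, measure at two or more fields and use
`taueff tau rexfit`.

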