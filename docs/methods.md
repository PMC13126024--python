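# Methods

## Kinetic scheme

The simulator implements the minimal ATP-dependent ligase cycle with an
abortive branch, in eight mass-action states:

```
E + S  <->  E·S(open)  <->  E·S(closed)       binding (k_bind), clamp (k_close/k_open)
E·S(closed)   ->  E·I(closed)                 AMP transfer, k_transfer(Mg)
E·I(closed)  <->  E·I(open)                   clamp dynamics (k_open/k_close)
E·I(open)     ->  E + I                       abortive ligation, k_diss
E·S(open)     ->  E + S                       unproductive binding, k_diss
E·I(closed)   ->  E + P                       nick sealing, k_seal(Mg)
```

`S` is nicked DNA, `I` the released AMP-DNA intermediate, `P` sealed
product. Adenylylation (step 1) is collapsed to instantaneous re-charging of
free enzyme: assays contain 0.2 mM ATP, far above the nM enzyme, so the
apo-enzyme lifetime is negligible and including it would only add an
unobservable state. Released AMP-DNA is a dead-end pool for the same reason:
a free ligase re-adenylylates before it can re-engage the blocked nick.

Both chemical steps carry single-site Mg²⁺ activation,
`k = k_max·[Mg]/(K_mg + [Mg])`, with separate half-activation constants
`K_mg_step2 < K_mg_step3` (transfer binds Mg²⁺ more tightly than sealing, so
lowering Mg²⁺ starves sealing first and channels flux into the abortive
branch). Clamp dynamics are taken Mg-independent; the conformational effect
of the cofactor is represented through the competition between the
Mg-sensitive chemical exits and the Mg-insensitive dissociation exits.

Gel observables pool enzyme-bound and free species, as a denaturing gel
does: band `s = S + E·S`, band `i = E·I + I`, band `p = P`.

### Branching identity used for validation

Once a molecule reaches `E·I(closed)`, the probability of aborting is

```
q = (k_open·k_diss/(k_close+k_diss)) / (k_seal + k_open·k_diss/(k_close+k_diss))
```

and because every pre-transfer dissociation returns substrate to the free
pool, the long-time abortive fraction of *all* DNA equals `q` regardless of
binding kinetics. The test suite checks the integrated trajectories against
the absorbing-state probabilities of the full rate matrix (computed by an
independent linear solve) to 1e-5 relative.

### Backends and numerics

The default backend integrates the stiff mass-action system with LSODA at
`rtol = 1e-10`, `atol = 1e-13·[DNA]` — tight enough that mass conservation
holds to 1e-8 in fraction units, which the tests assert. Integration
failures and negative states beyond 1e-7·[DNA] raise a diagnostic error
naming the parameter set. An exact-stochastic (Gillespie) backend is
provided for small copy numbers; it shares the reaction network and is
cross-checked against the deterministic branching within Monte-Carlo error.

### Default rate constants

The published work reports no microscopic rate constants, so the presets are
chosen to reproduce the *observable* regime rather than any fitted values:
sealing is rate-limiting (fast binding, fast transfer), the wild-type enzyme
on the canonical nick turns over at ≈0.95 s⁻¹ with K_Mg ≈ 1.1 mM and ≈5 %
abortive ligation at 1.0 mM free Mg²⁺, and destabilising the closed clamp
(higher `k_open`, higher `k_diss`, as for the K845N variant) or presenting
the damaged substrate (much higher post-transfer `k_diss`) pushes the
abortive fraction into the 0.4–0.99 range at low Mg²⁺. With sealing
rate-limiting, the effective turnover over an Mg titration is close to a
hyperbola in Mg with K ≈ K_mg_step3; the Mg-independent abortive exit adds a
competing loss that biases the apparent K slightly downward (≈7 % for the
wild-type presets), which is why mechanism-based parameter recovery is
asserted at ±15 % rather than exactly.

## Synthetic data

Two generators emit the band-record CSV schema
(`variant, substrate, replicate, time_s, enzyme_nM, dna_nM, atp_mM,
mg_free_mM, intensity_s, intensity_i, intensity_p`):

- `generate_dataset` — full mechanism simulation over a design grid of
  conditions × times × replicates.
- `generate_hyperbolic_dataset` — a phenomenological steady-state model
  whose effective turnover is *exactly* `k_cat·[Mg]/(K_Mg+[Mg])` with a
  constant abortive partitioning in the linear phase. This is the generator
  for parameter-recovery studies, where the generating K½ must be known
  exactly. Defaults: k_cat = 0.95 s⁻¹, K_Mg = 1.1 mM, 1 nM enzyme, 1000 nM
  DNA, 0.2 mM ATP, 3 replicates, gel noise σ = 0.02.

Gel-quantification error is modelled as additive Gaussian noise of standard
deviation σ on each band fraction, clipped at zero and renormalized to sum
to one per lane (inputs are assumed background-corrected; image analysis is
upstream of this package). The RNG is a single top-level seed split
hierarchically per condition and replicate, so any sub-stream is
reproducible in isolation.

Sampling design: quench times default to 12 points spanning each condition's
linear phase evenly in product fraction up to F_p = 0.19
(`linear_phase_times`), the standard practice of choosing timepoints per
condition after a pilot run. The default Mg grid is 10 levels over
0.1–5 mM, denser below 1 mM where the activation curve bends. Under these
study conditions (σ = 0.02, 3 replicates) the full pipeline recovers the
generating K½ within ±15 % in ≈96 % of trials; with sparser global time
grids the velocity errors at fast conditions dominate and recovery degrades,
which the sampling design is there to avoid.

What the generators do *not* emulate: lane-to-lane loading variation,
background subtraction residuals, saturated bands, pipetting error on the
concentration axes, and any correlation of errors between the three bands of
a lane beyond the renormalization constraint. Passing tests therefore
demonstrate correctness of the analysis chain under the stated error model,
not robustness to every failure mode of real gels.

## Analysis choices

- **Fraction observables.** `F_p = p/(p+s+i)` uses all three bands;
  `F_abort = i/(p+i)` conditions on AMP transfer having occurred and is
  undefined (a distinct error) when `p+i = 0`. All fraction operations are
  scale-invariant, so arbitrary fluorescence units are fine.
- **Abortive fraction per condition** is computed by pooling `i` and `p`
  over the linear-phase lanes (F_p below threshold): the steady-state
  partitioning is constant in the linear phase, so pooling reduces noise. A
  per-timepoint mode exists for exploration; endpoint-based estimates are
  not used because late lanes mix in substrate exhaustion.
- **Initial rates** are ordinary least squares with a free intercept
  (quench dead-time and background produce small offsets) through points
  with `F_p < 0.20`; the threshold is configurable. At least 3 in-window
  points are required; estimates carry R², an SE, and warning flags for
  negative slopes (beyond 2 SE) and for DNA:enzyme < 5 (fewer than ~5
  turnovers, outside the multiple-turnover regime). Velocity conversion
  multiplies the fraction slope by *total* DNA, since F_p is per total DNA.
- **Active-site titration** fits a continuous two-segment model
  `y = a + b·min(x, x₀)` (rising line, then plateau) by profiling the
  breakpoint over the data x-values and refining with bounded scalar
  minimization; ties go to the smaller breakpoint, making the fit
  deterministic and grid-oracle-checkable. If the two-segment model does not
  beat a single line by at least 1 % of its SSE, or the breakpoint lands at
  the titration edge, the data contain no detectable plateau and the fit
  refuses with advice to widen the titration. Active fraction =
  plateau / breakpoint (nominal axis as pipetted).
- **Saturation fits** use Levenberg–Marquardt (trust-region with positivity
  bounds) with data-driven starting values (k_cat₀ = max v, K₀ = x at
  half-max by interpolation) and tight convergence tolerances (1e-14), which
  noiseless round-trip tests pin to 1e-6 relative. Weights are 1/SE² when
  rate SEs are supplied, otherwise unweighted; parameter SEs come from the
  residual-scaled covariance, so equal weights reproduce the unweighted fit
  exactly. A single-site hyperbola is used for the Mg dependence — the
  enzyme binds several Mg²⁺ ions, but the activation data behave as a single
  essential cofactor site; a Hill exponent is available behind a flag for
  exploration only. Degenerate designs are flagged, not guessed at:
  `saturated_design` when velocities barely vary (K unidentifiable) and
  `extrapolated_K_half` when K exceeds 10× the largest tested concentration.
  Individual slightly negative velocities (noise around zero at
  near-unreactive conditions) are retained with a flag rather than rejected,
  so a noisy low-signal condition cannot abort a whole pipeline run.
- **Replicate handling** defaults to pooling per-replicate velocities as
  separate weighted points; averaging replicates first is available. Both
  are exposed because reported means ± SDs of ≥3 replicates do not dictate
  either choice.
- **Fidelity decomposition.** Overall discrimination is the ratio of
  catalytic efficiencies (canonical/damaged); step 3 is the ratio of sealed
  fractions; step 2 is derived from the identity overall = step2 × step3, so
  the identity holds by construction (asserted to 1e-12). A cross-check
  route computes step 2 directly from abortive-inclusive efficiencies and
  must agree. Errors combine in quadrature on the relative scale
  (`SE_rel = √Σ SE_rel²`), treating conditions as independent (separate
  reactions); this is exact for independent log-normal errors and matches
  Monte-Carlo propagation within a few percent for CVs ≤ 0.3. A damaged
  sealed fraction of exactly zero yields a censored lower bound
  (`F_sealed,canonical / SE_damaged`), never a pseudo-infinite number.
  Fold-factors are reported at 2 significant figures with full precision
  retained internally.
- **Mg bookkeeping.** Conditions are labelled by *free* Mg²⁺; a helper
  converts total to free by subtracting 1:1 ATP-chelated Mg²⁺
  (`free = total − ATP`), the tight-chelation model appropriate at these
  concentrations. The pipeline accepts either convention via `mg_mode`.

## Pipeline and reproducibility

`run_pipeline` composes quantify → rates → saturation fits → fidelity and
writes plain CSV/JSON artifacts with frozen column names, a run manifest
(config, seed, package version), and a human-readable summary. Outputs are
byte-identical across reruns of the same inputs and configuration; CSVs are
written at 15 significant digits and read back with round-trip float
parsing, so write-then-read is lossless at that precision. When a stage's
inputs are missing (e.g. no damaged-substrate conditions), the stage is
skipped with an explicit log line and all other outputs are still produced.

## Validation problem sizes

The test suite validates: branching against the absorbing-state oracle on 20
random schemes (1e-5 relative); mass conservation at 1e-8; fit round-trips
at 1e-6 and optimizer-vs-grid-search agreement at 1e-4 on 20 random
parameter pairs; end-to-end K½ recovery on 100 seeded trials of the default
study design; and quadrature-vs-Monte-Carlo agreement (10⁵ samples) within
10 % for CVs ≤ 0.3. These sizes keep the whole suite under ~10 s while
leaving each assertion statistically meaningful.

## Known limitations

- Microscopic presets are regime-matched, not fitted; quantitative agreement
  with any particular enzyme preparation is not claimed.
- The high-affinity non-catalytic Mg²⁺ (HiFi) site is not modelled as a
  separate species; its fidelity contribution is absorbed into the
  substrate-dependent dissociation rates.
- No progress-curve (integrated rate equation) or pre-steady-state fitting;
  the analysis is strictly initial-rate.
- Unproductive binding (dissociation before AMP transfer) is a distinct flux
  in the simulator but is invisible in the band observables, exactly as in
  the assay — the tables cannot distinguish it from non-binding.
- Error propagation is first-order quadrature; no bootstrap or Bayesian
  intervals.
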