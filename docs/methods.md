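# Methods

## The systems being modeled

`fuelcircuits` models two dissipative DNA-gated bioreactor circuits. In both,
a glucose-oxidase-loaded ZIF-90 nanoparticle carrying a DNA tether (G), a
hemin-G-quadruplex DNAzyme strand (B) and a linker strand transiently
assemble into a catalytically active supramolecular complex (C). The complex
channels GOx-generated H2O2 to the DNAzyme, which oxidizes Amplex-Red to
fluorescent resorufin (or luminol to chemiluminescence). An added fuel
strand drives the system out of its resting state; an enzyme consumes the
fuel, so the complex forms transiently and the module relaxes back to rest.

**Nickase circuit** (strands labeled 1–5): the fuel (5) invades the blocker
duplex TL = (3)/(4) by toehold-mediated strand displacement, releasing the
linker T (3) which bridges G (1) and B (2) into C. The nicking endonuclease
(Nt.BbvCI class) cleaves the fuel inside the displaced duplex (4)/(5); the
liberated strand L (4) then strips T back out of C, restoring TL and the
resting module. Reactions:

    R1   TL + F  -> LF + T          k_displace        (uM^-1 h^-1)
    R2a  G + T   -> GT              k_bind_tether     (uM^-1 h^-1)
    R2b  GT + B  -> C               k_bind_quadruplex (uM^-1 h^-1)
    R3   LF  --N-->  L + W          k_nick            (uM^-1 h^-1, bilinear)
    R4   C + L  -> G + B + TL       k_disassemble     (uM^-1 h^-1)

**Exonuclease III circuit** (strands 6–8): the fuel T2 (8) directly bridges
G (6) and B (7) into C. Exo III digests the fuel only inside the assembled
complex (where its 3' end is recessed), releasing both constituents intact;
the G-quadruplex strand is engineered with a 3' single-strand tether and is
never a substrate.

    R1a  G + F   -> GT              k_bind_tether
    R1b  GT + B  -> C               k_bind_quadruplex
    R2   C  --E-->  G + B + W       k_digest

All species carry an explicit multiset of strand labels; waste retains the
composition of what it was cut from. This makes every strand total (and
every enzyme) an exact linear conservation law, verified symbolically at
network construction (integer orthogonality against every stoichiometry
vector) and numerically along every trajectory (drift < 1e-6 relative).

## Model variants

* `assembly="sequential"` (default) splits three-component assembly into two
  bimolecular steps through a tether–linker intermediate GT.
  `assembly="lumped"` uses a single effective step G + B + T -> C with
  mass-action rate k·[G][B][T]; a one-step trimolecular encounter is not
  elementary, but at the 1 uM scale it is a serviceable effective law and
  removes one weakly constrained parameter when fitting.
* `enzyme_law="linear"` (default) uses the bilinear flux k·[E]·[S],
  appropriate when substrate is well below Km; `"mm"` switches to the
  Michaelis–Menten form k·[E]·[S]/(Km+[S]) with Km in uM.
* `digest_intermediate` (Exo III only, off by default) adds digestion of the
  partially assembled GT intermediate for sensitivity analysis.

Units are fixed package-wide: concentrations uM, time h, bimolecular
constants uM^-1 h^-1 (the lumped assembly step: uM^-2 h^-1), Km in uM.
K+-dependent quadruplex folding is taken as instantaneous (K+ in excess),
and the background activity of separated constituents appears only as the
calibration background, not as circuit reactions.

## Simulation and measurement model

Trajectories are integrated with `scipy.integrate.solve_ivp` (LSODA,
rtol 1e-8, atol 1e-12 uM, dense output); the nM-scale enzyme against uM
strands spans ~2 decades, which LSODA handles without tuning. Output states
are clipped to zero after verifying no excursion below -1e-9 uM.

The measurement process emulates withdrawn aliquots read on the default grid
{0, 1, 2, 4, 6, 8, 10} h. The full biocatalytic cascade is lumped into a
linear calibration `reading = slope·[C] + background` (defaults 150
units/uM, 10 units); the inverse calibration floors estimates at zero. The
same linear contract serves the fluorescence and chemiluminescence channels
with their own slope/background.

Transient features: `peak_time` is the argmax of the complex over a fine
resampling of the dense solution; `depletion_time` is the first time after
the peak at which the complex falls to 5% of the peak value (None if never
reached within the horizon). Simulation horizons (24 h nickase, 16 h
Exo III) are long enough to resolve the slowest depletion on the enzyme
grids.

## Default rate constants

The fitted constants of the original experiments are ingested from a
user-supplied YAML file when available (`default_true_constants(circuit,
config_path=...)`, source tag `"config"`). The built-in defaults (source
`"builtin"`) are not fitted to any measurement; they were chosen once so
that each base-condition transient reproduces the designed qualitative
shape — rise over ~2 h, nickase depletion to 5% of peak near 10 h, Exo III
near 8 h — and so that the fuel/enzyme grids show the designed monotone
orderings. With the defaults, the nickase base run peaks at 1.96 h
(0.42 uM) and depletes at 10.4 h; Exo III peaks at 1.85 h (0.41 uM) and
depletes at 8.4 h.

## Synthetic data

`generate_transient_dataset` simulates each condition, samples the
withdrawal grid, applies per-sample Gaussian noise on the readout scale
(default: proportional, sigma 5% of the reading — replicate variability of
the emulated measurements is not documented, so a typical plate-reader
level was adopted), floors negative readings, and inverts the calibration.
One `numpy` generator seeded from the noise model drives the entire stream,
so datasets are bit-reproducible per seed.

What the generator does **not** emulate: instrument-level emission spectra,
slow drift or pipetting bias between withdrawals (noise is independent per
sample), depletion of glucose/O2/reporter substrates, and particle-surface
heterogeneity. Passing tests therefore demonstrate correctness of the
kinetic and statistical machinery under the stated noise model, not
robustness to every artifact of real plate data.

## Inference

`fit_rate_constants` minimizes squared residuals between simulated and
observed complex concentrations (after calibration inversion — the loss
lives on the concentration scale) at the withdrawal times, jointly over any
number of conditions. Parameters are optimized as log10 values (they are
positive and span decades) within bounds, via lmfit's trust-region
least-squares. A seeded multistart (default 8 starts, log-normal spread of
0.5 decades around the guess) makes the procedure deterministic per seed;
the objective trace records the best cost so far, hence is non-increasing.
Standard errors are propagated from the log-space covariance
(se_k = k·ln10·se_log10) and reported as None when the covariance is
unavailable. The fit hot path integrates only to the withdrawal times
(no dense output), which roughly halves its cost.

Identifiability: with `profile="fast"` each free parameter is perturbed
±50% at the optimum; if the residual norm moves by <1% the parameter is
flagged non-identifiable rather than silently reported as precise (this is
what catches zero-flux pathways, e.g. digestion constants in an enzyme-free
run). `profile="full"` re-optimizes the remaining parameters at each
perturbed value — a true profile likelihood that also exposes sloppy
*combinations* — at roughly 5x the fit cost.

### A note on sloppiness and the recovery study

At the default constants the complex assembles and disassembles fast
relative to the 1–2 h sampling grid, so the complex is near quasi-steady
state: the data sharply constrain the *ratio* of the assembly and
disassembly constants but only weakly their absolute values. At 5%
measurement noise the per-realization scatter of those two constants is
30–70%, while k_nick is recovered to <10%. The end-to-end Monte-Carlo
recovery study therefore validates the estimator's central tendency: over
20 noise realizations the median estimate of every constant must fall
within 25% of the generating value (measured: ≤17%), with single-run
uncertainty reported through the standard errors. At zero noise a single
fit from a 3x-perturbed guess recovers all constants essentially exactly.

## Numerical choices and edge cases

* Negativity guard: the compiled RHS raises on states below -1e-6 uM when
  called directly; inside `simulate` the guard is loosened to -1e-3 uM
  (solvers probe trial states) and a violation is converted into an
  `IntegrationError` with diagnostics.
* Zero-information data (identically zero complex estimates) and
  single-time-point observations are rejected with a `ValidationError`
  before any optimization.
* Flat or monotone trajectories return `depletion_time = None`; an
  all-zero trajectory additionally returns `peak_value = 0`.
* Ties in the peak search resolve to the earliest grid time (argmax).
* CSV artifacts are UTF-8 with a comment header stating units; YAML configs
  are validated with every violation aggregated into one error.

## Known limitations

* Rate laws are effective, not sequence-derived; no thermodynamic
  prediction of displacement rates and no spatial/diffusion modeling of the
  particle surface.
* The reporter cascade is a static linear map. A derived-rate readout
  (signal proportional to the instantaneous resorufin production rate,
  itself proportional to [C]) is representationally identical to the linear
  calibration with the slope reinterpreted as readout·h^-1 per uM, so no
  separate code path exists for it.
* The lumped assembly variant uses a termolecular effective law; its
  constant is not comparable in units to the sequential pair.
* Joint fitting of fluorescence and chemiluminescence channels shares one
  constant set only if the caller passes both datasets; per-channel
  calibrations are the caller's responsibility.
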