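# Methods

## Model

The package simulates the core negative feedback loop between the tumor
suppressor p53 and its inhibitor Mdm2. Four species are tracked: free
nuclear p53 (`p`), mdm2 mRNA (`m_m`), free Mdm2 protein (`m`) and the
p53–Mdm2 complex (`c`), all in nM, with time in hours. The rate
equations are

    dp/dt   = σ − α·p − k_f·p·m + (k_b + γ)·c
    dm_m/dt = k_t·p² − β·m_m
    dm/dt   = k_tl·m_m − γ·m − k_f·p·m + (k_b + δ)·c
    dc/dt   = k_f·p·m − (k_b + δ + γ)·c

p53 is produced at a constant rate σ and removed Mdm2-independently at
rate α. Mdm2-dependent degradation (rate δ) acts on p53 bound in the
complex and releases free Mdm2; Mdm2 turnover (rate γ) is identical for
free and bound Mdm2, and a γ event on the complex releases free p53, so
the Mdm2 half-life does not depend on binding. p53 transactivates mdm2
with a Hill coefficient of 2 (double binding site at the mdm2 promoter),
giving the unsaturated activation term k_t·p² (consistent with the
nM⁻¹h⁻¹ units of k_t). There is no explicit transcriptional delay:
oscillations arise solely from the nonlinearity of complex formation
(sequestration), so the loop is a four-dimensional ODE system, not a
delay system.

An alternative convention in which the γ event destroys the whole
complex is available everywhere as `variant="codegradation"`. At default
parameters it shifts the resting state by under 2% and moves the
oscillation onsets only marginally; the release convention is the
default because it keeps the bound-p53 budget explicit, and the ≈100 nM
resting total p53 validates it.

Default rate constants: σ=1000 nM/h, α=0.1/h, δ=11/h, k_t=0.03 nM⁻¹h⁻¹,
k_tl=1.4/h, β=0.6/h, γ=0.2/h, k_b=7200/h, k_D=k_b/k_f=1.44 nM (so
k_f=5000 nM⁻¹h⁻¹). k_D is treated as the independent quantity alongside
k_b: any change to k_D rewrites k_f with k_b fixed. At these defaults the
unique admissible equilibrium has p≈16.78 nM, c≈90.76 nM — a resting
total p53 of ≈107.5 nM, with most p53 Mdm2-bound and a high turnover.

## Equilibria and stability

The equilibrium system reduces exactly to one scalar equation: at a
root, m_m=(k_t/β)p², m+c=(k_tl k_t)/(γβ)·p², c=k_f·p·m/(k_b+δ+γ), and
the p53 balance σ=α·p+δ·c closes the system. The residual is strictly
decreasing in p, so the admissible equilibrium is unique; it is found by
bracketed root-finding (Brent) on p∈[10⁻⁶,10⁴] nM with relative
tolerance 10⁻¹⁰. Stability comes from the eigenvalues of the analytic
Jacobian; the real-part threshold is 10⁻⁸ h⁻¹. Doubling γ destabilizes
the equilibrium through a complex-conjugate pair (the Hopf onset lies
between 1- and 2-fold γ), which is where oscillations appear.

## Time courses and oscillation metrics

Simulations use `scipy.integrate.solve_ivp` with LSODA and the analytic
Jacobian (the k_b=7200/h binding cycle makes the system stiff), relative
tolerance 10⁻⁸ and absolute tolerance 10⁻⁶ nM, sampled on a 0.01 h
output grid. Stress events are parameter switches applied exactly at
their event times by restarting the integration.

Metrics are computed on the trailing half of a run (settle fraction
0.5). Amplitude is max−min over the settled window; spikyness is
amplitude/average, and oscillations with spikyness ≥ 2 are "spiky" (the
boundary is included). A window whose amplitude is below 10⁻³ of its
average counts as steady. Peaks are local maxima with a prominence floor
of 1% of the window range and a minimum separation of 0.25 h (to ignore
solver ripple), refined below the grid by local quadratic interpolation.
The standardized classification protocol starts from the parameter set's
own resting state when one exists, otherwise after a 200 h
pre-equilibration, and analyzes a 200 h run.

## Stress scenarios

Stresses act as per-parameter fold changes: nutlin raises k_D only; DNA
damage raises γ and k_D and lowers δ; hypoxia lowers k_t and δ; oncogene
activation and nitric oxide lower δ; ribonucleotide depletion raises σ.
The published record fixes only the directions, so non-calibrated
stresses default to 5-fold in the printed direction (overridable), which
keeps cross-stress comparisons at matched magnitudes.

The DNA-damage magnitudes are calibrated against the ionizing-radiation
peak schedule: first free-p53 peak at 0.5 h, second at 6 h, third inside
[9, 13] h, with the first peak about twice the second and about 2.5
times the third. The loss is the sum of squared relative errors on
(t₁, t₂, h₁/h₂, h₁/h₃) plus a hinge penalty for t₃ outside [9, 13] h,
minimized over γ∈[1,50], δ∈[1/50,1], k_D∈[1,50] (multipliers) by a
7-point-per-axis log grid followed by Nelder–Mead refinement in log
space — fully deterministic. The fitted folds (γ×1.393, δ×0.958,
k_D×4.17) achieve peaks at 0.51, 6.03 and 11.0 h with height ratios 2.03
and 2.47, and ship as the packaged `dna_damage` scenario.

SNP309 in the mdm2 promoter is modelled as a k_t increase: the G allele
raises mdm2 transcription, so GG multiplies k_t by `g_fold` and TG by
√g_fold (a geometric allele dosage; no quantitative dosage is
published). Each genotype rests at its own equilibrium before stress.

## Phase diagrams and sensitivity

Phase diagrams evaluate the standardized protocol on a 2-D (log) grid;
per-cell failures are recorded, never fatal. The spikyness=2 contour is
extracted by marching squares on the spikyness field with linear
interpolation along (log-)axes; disconnected pieces are kept.

Sensitivity curves vary one of {σ, α, δ, k_t, γ, k_D} over log-spaced
folds covering exactly [1/5, 5] (fold 1 included, response normalized to
1 there) and report the settled average free-p53 level. β and k_tl are
excluded because time and mRNA units can be rescaled to set β=k_tl=1.
Two slope summaries are computed. The *local* summary (max absolute
log-log finite difference) is diagnostic: it reproduces the flat stretch
of the γ curve between 1- and 2-fold, where the average barely moves
although the peak level keeps rising. It is, however, a poor ranking
statistic: below the k_D onset (fold ≈0.69) spiky oscillations reshape
the waveform and the local slope of the average (≈0.84) reflects that
reshaping rather than how strongly the parameter drives the p53 level.
Parameter ranking therefore uses the *overall* log-log chord across the
full fold range, which orders the parameters σ≈δ (0.47) > γ≈k_t (0.38)
≫ k_D (0.23) ≫ α (0.001): the average level responds far more to γ, δ,
k_t and σ than to α or k_D.

## Stochastic layer

The exact Gillespie direct method runs on the ten-channel translation of
the rate equations; summed mean-field rates reproduce the ODE right-hand
side up to the O(1/Ω) combinatorial correction of the transcription
channel, which uses the pair count n_p(n_p−1) (Hill-2 activation is
dimer occupancy). Concentrations convert to copy numbers through
Ω = V·N_A·10⁻⁹; the reference volume is a sphere of radius 6 μm
(9.05×10⁻¹³ L, Ω≈544.9 molecules/nM), at which the ≈100 nM resting
total p53 is ≈54,500 molecules. Initial counts are the nearest integers
of concentration×Ω. Per-run seeds derive from a `numpy.SeedSequence`
spawn of the ensemble seed, and every output records its seed.

Peak statistics on count trajectories use a 0.5 h moving-average
pre-smoother and a coarser detector (2 h minimum separation, 10%
prominence floor). The 0.5 h window is an order of magnitude below the
~5.5 h inter-peak interval but wide enough to suppress shot noise at the
few-tens-of-molecules level of a 500-fold-reduced volume; narrower
windows lock onto noise wiggles there. With these settings the ensemble
mean schedule at 500-fold reduction matches the deterministic one
(first peak near 0.5 h, second near 6 h) and the peak-time standard
deviation increases with peak index — later peaks are far more variable
than the first, while at large volumes trajectories become
indistinguishable from the ODE.

### Problem sizes

The event count of the exact direct method is set by the binding cycle:
during the DNA-damage response at the reference volume the total
propensity integrates to ≈9×10⁹ events per 12 h run (k_b·c·Ω alone is
~8×10⁸/h), i.e. ≈1.8×10¹¹ exponential variates for a 20-run ensemble —
far beyond desk scale even for the compiled kernel (~1.8×10⁷ events/s).
The packaged convergence check therefore runs the 20-run ensemble at a
50-fold-reduced volume (≈1,100 total-p53 molecules, ≈3.6×10⁹ events,
minutes of compute), where the ensemble mean still tracks the ODE within
3% in sup-norm; the noise-variability analysis runs at the stated
500-fold reduction in full. Convergence is monotone in volume, so
agreement at Ω/50 bounds the deviation at Ω from above.

## SBML exchange

Models export as SBML Level 3 Version 2 with explicit nM and hour units
and a reaction-based encoding identical to the stochastic channel
decomposition, so the ODE, SSA and SBML views share one source of truth.
Import parses the MathML subset the writer emits into sympy expressions;
a term-level diff reporter expands both right-hand sides in the monomial
basis and reports non-cancelling terms, so a foreign document (e.g. a
public-database copy of the model) is reconciled explicitly rather than
silently overwritten.

## Known limitations

* The deterministic layer is well-mixed, single-compartment and
  nuclear-only; α lumps export, sequestration and basal degradation.
* Stress magnitudes other than DNA damage are conventions (5-fold), not
  fits; only their directions are constrained by the biology.
* The stochastic layer models intrinsic reaction noise only. At
  realistic copy numbers that noise is negligible, so the observed
  cell-to-cell variability must come from extrinsic sources the model
  does not represent; the 500-fold volume reduction is an ad-hoc device
  to expose the qualitative peak-variability ordering, not an estimate
  of real noise levels.
* Downstream physiology (arrest vs apoptosis) is outside the model; the
  outputs are p53 levels and dynamics only.
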