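# Methods

## Conductance-voltage analysis

Steady-state current is the mean over an end-of-sweep window (default the
last 10 ms of a 100-ms step; configurable). Conductance is the ohmic ratio
`G = I/(V − V_K)` with the K⁺ reversal potential fixed per dataset (default
−80 mV); the ratio is carried in the µA/mV units of the inputs, as in
standard practice for this assay. Points recorded at `V = V_K` have zero
driving force and are dropped with a warning rather than interpolated.

Boltzmann fits `G(V) = G_MAX/(1 + exp((V_½ − V)/s))` use unweighted
nonlinear least squares (Levenberg–Marquardt via `scipy.optimize.curve_fit`)
with data-driven starting values: `G_MAX` from the observed maximum, `V_½`
from the voltage nearest half-maximum, and `s` from the 25–75% rise width
divided by 2.2 (the exact factor for a logistic rise). Bounds keep
`G_MAX ≥ 0` and `s > 0`. Non-convergence is flagged, not raised; a flat
curve is rejected because its parameters are undefined. Whether per-point
weighting was appropriate is left to the caller (a `weights` argument);
the default is unweighted, matching common practice. Fits of normalized
curves are unnecessary: normalization is presentation-only and the fit runs
on raw conductance.

Group comparisons of shifts use the two-tailed unpaired t test, Welch
variant by default because group sizes in these assays are small and
unequal (n = 2–10); the pooled-variance form is available via
`equal_var=True`.

## Concentration-response

The shift at concentration `c` follows `ΔV(c) = ΔV_MAX/(1 + EC50/c)` — a
rectangular hyperbola with Hill coefficient fixed at 1; no Hill-slope
parameter is added. Fitting is unweighted least squares in linear
concentration space; EC50 is initialised at the concentration whose shift
lies nearest half of the extreme observed shift, and ΔV_MAX slightly beyond
that extreme. Standard errors come from the Jacobian-based covariance at
the optimum. All-equal shifts leave EC50 unidentifiable and are flagged
rather than fitted. Efficacy comparisons report the percent change in
|ΔV_MAX| between two fits.

## Additive binding-site model

Each mutant's shift at a single test concentration (100 µM in the packaged
panel) is modelled as `ΔV = ΔV_S3/S4 + ΔV_S4/pore + ΔV_Residual` under the
constraint structure: the S3/S4 term is a single value active only in
channels carrying the 2R motif; the S4/pore term takes one value per pocket
configuration class (WT, R362Q, W454A, R362Q/W454A); the residual is common
to all mutants. Mutants touching further pocket residues (R365Q, F416A) are
assigned extended classes with a warning instead of being forced into the
four canonical ones, so the class registry grows with the panel. An
optional variant zeroes the pore term whenever the 2R motif is present,
encoding the observation that the S3/S4 site dominates in 2R channels;
both variants use the same fitting machinery.

The model is linear, so fitting is linear least squares on a binary
indicator design (optionally 1/SEM²-weighted; default unweighted).
Because every row contains the residual indicator and exactly one pore
indicator, the design is generically rank-deficient by one: only sums of
the residual with each pore value are determined. The fitter returns the
minimum-norm solution in that case, and the honest uncertainty lives in
`solution_ranges`: for each parameter, the interval attainable by any
parameter vector whose SSE is within a tolerance (default 5%) of the
minimum. Along the row space of the design the extent has the closed form
`sqrt(tol)·‖S_r⁻¹ V_rᵀ e_i‖` from the SVD; any null-space component makes
the interval unbounded, which is flagged, unless a box on the parameters is
supplied, in which case the ridge extent is resolved by linear programming
over the null-space coordinates (row-space and ridge extents are combined
additively, a slightly conservative construction). Parameters may be pinned
exactly via `fixed=`; the packaged Wu50 reproduction pins the residual at
−10 mV, which restores full rank and yields S3/S4 ≈ −16.6 mV and pore
contributions of −14.4 (WT), −33.5 (R362Q), −5.8 (W454A) and −30.5
(R362Q/W454A) mV on the eight-mutant panel.

The eight-mutant panel is the full 2×4 factorial of {±2R} × {four pore
classes}. One of its entries (2R/W454A) is not reported as a numeric mean
with SEM; it is reconstructed from the stated 32-mV increment of the 2R
motif on the W454A background and flagged `status=inferred` in the fixture.
Rows whose shift could not be measured (maximal conductance collapse) are
carried with `status=gmax_block` and excluded from fits by default, never
dropped silently.

## MD contact analysis

For each (residue, subunit) pair the per-frame minimum over all
heavy-atom pairs between ligand and residue is computed by direct
broadcasting (hydrogens excluded by element, falling back to an `H` name
prefix); with box vectors present, orthorhombic minimum-image corrections
are applied, and toys without a box use plain Euclidean distances. Contact
frequency is the exact rational `k/n_frames` with the boundary counted as a
contact (`distance ≤ cutoff`, reading "within 4.5 Å" inclusively — ties
have measure zero in real data). The default cutoff is 0.45 nm; the CLI
accepts Å explicitly. All frames of the supplied coordinate file count as
production time unless `--skip-frames` trims the start. The four chains of
the tetramer are treated as quasi-independent replicates and reported
separately. Trajectory reading (PDB topology + XTC/DCD coordinates) goes
through mdtraj; chlorines and all other non-hydrogen ligand atoms count as
heavy atoms.

## Synthetic data

The generators realise exactly the structure the fitters assume, so
noiseless generation followed by fitting is an identity up to solver
tolerance — the basis of the round-trip tests.

* **Current families**: `I(t,V) = leak + G(V)·(V − V_K)·(1 − e^(−t/τ))`
  with a voltage-independent activation time constant (τ = 5 ms default;
  kinetics are not analysed downstream, only the steady-state window) and
  additive i.i.d. Gaussian noise per sample. Defaults describe a
  Shaker-like channel: midpoint −30 mV, slope 10 mV, steps −80…+50 mV in
  10-mV increments from −80 mV holding, V_K = −80 mV.
* **Dose-response tables**: replicate shifts per concentration around the
  hyperbola, summarised as mean ± SEM; defaults use the Wu50/WT parameters
  (EC50 29.1 µM, ΔV_MAX −36.1 mV). Replicate scatter is i.i.d. Gaussian —
  the simplest model consistent with reported SEMs; the raw per-cell
  scatter of the real assay is not asserted, so `noise_sd` is a free
  parameter.
* **Shift panels**: additive site sums per mutant plus Gaussian noise.
* **Toy trajectories**: one pseudo-atom per residue per subunit on a
  widely spaced axis grid, and a ligand with one dedicated heavy anchor
  atom per (residue, subunit) slot toggled between 0.6·cutoff and
  spacing/2 in a seeded random choice of `round(fraction·n_frames)` frames.
  A single rigid ligand translated along one axis cannot realise
  independent per-residue fractions, hence the per-anchor toggling; one
  ligand hydrogen permanently inside the first pair's cutoff verifies that
  hydrogens never count. No physical realism is attempted — geometry,
  forces and kinetics are meaningless beyond the contact schedule.

What passing tests show about real data: the estimators are exact on data
that satisfy their model assumptions and unbiased at realistic noise; they
do not probe leak/capacitive artifacts, kinetic model mismatch,
non-Gaussian scatter, or binding-site interactions beyond additivity (the
real panel's residual misfit at the W454A backgrounds is visible as SSE,
not hidden).

## Recovery study sizes

The stochastic recovery checks use, as the package's standard study
conditions: 100 replicate Boltzmann pipelines at current noise of 5% of the
maximal steady-state current; 1000 replicate EC50 fits at 1-mV shift noise
over six log-spaced concentrations spanning EC50/10…10·EC50; and 1000
replicate site-model fits at 2-mV measurement noise on a panel of 16
replicate measurements per construct (eight constructs). The 16-replicate
choice follows from the variance of the class estimators: with residual
fixed, each pore class is estimated from 2N measurements and the S3/S4 term
from all four class increments, giving parameter SDs of `sqrt(2.5/N)` mV at
2-mV noise — N = 16 puts the worst parameter near 0.4 mV, comfortably
inside the 0.5-mV target that a dedicated mutant-panel study would aim for,
while N = 5 (a typical single-paper panel) cannot resolve contributions to
better than ±0.7 mV.

## Known limitations

* The five-mutant reduced panels (used to compare compounds on equal
  footing) have no canonical membership here; generic subsetting plus
  `solution_ranges` replace them.
* Solution ranges combine row-space and ridge extents additively
  (conservative), and the ridge boxing requires user-supplied bounds.
* The trajectory reader infers subunits from chain order (A, B, C, …) and
  treats a single-chain topology as one subunit with a warning.
* No gating-current (Q-V) analysis, docking, trajectory generation, pose
  clustering or free-energy estimation.
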