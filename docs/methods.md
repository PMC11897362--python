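# Methods

## Model and integration

Local dynamics are Stuart–Landau oscillators in Cartesian form; the network
couples them diffusively through a symmetric nonnegative matrix C scaled by a
global gain G, so two nodes in identical states exchange nothing and the
homogeneous state is preserved. The control parameter a is shared by all
nodes (no regional heterogeneity) and may vary in time through a schedule
object; a = 0 is the supercritical Hopf point, with limit-cycle radius √a
above it.

Integration is Euler–Maruyama with step dt = 0.1 s by default. The additive
noise term γ η(t) is read as SDE noise amplitude: each step adds
γ√dt · 𝒩(0, 1) independently to the x and y components of every node. Initial
conditions are drawn uniformly in [−0.1, 0.1] from the seeded stream and a
60-s burn-in is discarded before recording starts; the recorded signal is x_n
sampled every tr = 2 s, deliberately unfiltered since node frequencies
already live in the 0.01–0.08 Hz band. A guard aborts with the offending step
if any |z_n| exceeds 10³. Identical seed and configuration reproduce
trajectories bit for bit; all derived seeds come from `SeedSequence`
substreams keyed by (repeat, cell, run) counters, so grid searches are
reproducible cell by cell and trivially parallelizable.

Explicit Euler inflates the limit-cycle radius by a factor ≈ 1 + dt·ω²/(4a),
which matters only for the amplitude-law checks at small a; those use
dt = 0.01 s and a 0.02-Hz node so the bias stays below 1%. Halving dt does
not move any fitted optimum at the scales used here.

## Schedule

The pharmacokinetic transient subtracted from baseline is λ·s·(τ e^{−τ/β})/N.
Time and β are in seconds: β = 284 s puts the deepest excursion ≈ 4.7 min
after injection. Two normalizer conventions are supported — `peak`
(N = β/e, the default: the deepest drop is exactly λ·s) and `integral`
(N = β²: the bracket integrates to one) — because the absolute scale linking
the printed λ range (≈ 65–160) to bifurcation units is a genuine modelling
choice; the default conversion s = 10⁻³ makes a λ ≈ 159 schedule dip from
0.07 to ≈ −0.09, i.e. across the bifurcation, which is the regime the whole
analysis is about. Both the convention and s are configurable.

## FCD and distances

Windows start at the first recorded sample and advance by the step while
fully contained in the series; a window belongs to the baseline block iff
start + length ≤ t_inject. This start-time convention yields 82 windows per
28-min session and a 22-window baseline block at the default 60/20-s layout.
Window FC is the Pearson matrix; a zero-variance row yields correlation 0
with a warning rather than an error, so degenerate synthetic inputs survive.
FCD entry (i, j) correlates the strictly-upper-triangular parts of FC(t_i)
and FC(t_j); the diagonal is fixed at 1 and kept in distance computations
(diagonal contributions cancel in differences). Distances are Frobenius norms
of matrix differences, optionally divided by the norm of the reference
matrix.

Phase-based summaries extract the analytic phase of the demeaned signal on
the full series before windowing, trimming one window length at each end
against Hilbert edge effects. Phase coherence is the time-mean of
cos(θ_i − θ_j) per window; synchrony and metastability are the time-mean and
time-SD of the Kuramoto order parameter R(t).

## Fitting

Baseline fitting sweeps constant (a, G) against the baseline FCD block;
temporal fitting fixes (a₀, G) = (0.07, 0.5) and sweeps (λ, β); a null
variant holds a constant post-injection value. Per cell, the simulated FCDs
of the runs are averaged first and the distance computed on the average (not
averaged per-run distances). The temporal sweep is repeated with fresh noise,
each repeat contributing one optimum; conditions are compared per parameter
with Welch's unpaired two-sided t-test and mean ± 1.96·SEM confidence
intervals. Ties at the minimal distance break toward the smallest first
parameter, then the smallest second. Cells whose simulation diverges are set
to NaN and excluded from the argmin with a warning.

Desk-scale defaults (20-node modular connectome, 5×5 grids, 3 runs per cell,
5 repeats) are the sizes at which the package's own recovery guarantees are
stated and tested; the study-scale grids (21×21 baseline, 41×45 temporal,
15 runs, 50 repeats, 90 regions) are plain parameter choices away.

## Perturbation and reactivity

The schedule is sampled at n equally spaced post-injection times (default 42
over 20 min; first sample one spacing after injection, last at the span
end). For each sampled a_p and forcing amplitude F_ext, a session runs with
a = a₀ through the 8-min baseline and a = a_p afterwards, while each target
node of the chosen RSN receives F_ext·(cos ω_n t, sin ω_n t) from the end of
the baseline; the cell records the normalized FCD distance M to the reference
target. The default F_ext grid is 0–0.015 in steps of 0.00125 (13 points).

χ(t_p) = ∂M/∂F_ext is computed per run with the second-order scheme — central
differences inside the grid, one-sided three-point stencils at the ends
(exact through quadratics) — divided by the RSN node count, referenced by
subtracting the first post-injection sample, and averaged over runs. Peak
values are summarized by bootstrap over runs (resample size = run count,
default 200 draws); the bootstrap SD estimates the standard error of the
peak, so its CI is mean ± 1.96·SD of the bootstrap distribution. The
receptor correlation bootstraps networks with replacement (default 1000
draws, degenerate resamples redrawn) and reports mean ± 1.96·SEM of the
bootstrap distribution, matching the much tighter interval appropriate for a
mean of 1000 draws.

The susceptibility-vs-criticality probe (`susceptibility_curve`) holds a
constant and measures the FCD distance between forced and unforced sessions
that share a noise realization (paired seeds), so the distance isolates the
forcing response; χ(a) is the mid-grid derivative of that response averaged
over paired runs. The probe uses weak noise (γ = 0.02) and weak forcing
(F_ext ≤ 0.01): susceptibility-peaks-at-criticality is a weak-noise,
linear-response statement, and stronger noise smears the transition enough to
blur the peak's location at 0.02 grid resolution. Under these conditions the
peak lands in the grid cell containing a = 0 on a 20-node network.

## Synthetic fixtures

Generators are pure functions of (parameters, seed). The connectome is a
modular weighted random graph (edge probability tripled within modules, a
weak ring backbone guaranteeing connectivity) rescaled by a symmetric
Sinkhorn-style iteration to unit node strength — only symmetry,
nonnegativity and normalized strength matter to the model, so no surrogate
tractography statistics are emulated. Frequencies are uniform in the
0.01–0.08 Hz band. The partition assigns nodes randomly to six RSNs with the
study's network sizes (7, 9, 26, 13, 12, 24; trimmed with a warning when
they exceed the region count, as at N = 90 where they sum to 91). Receptor
maps plant an exact sample Pearson correlation between network means and a
reference vector by mixing the z-scored reference with an orthogonalized
noise vector; per-region densities scatter around their network mean with
zero-sum jitter so the mean is preserved exactly.

"Empirical" FCD targets are averages of independent simulated subjects driven
by a known ground-truth schedule, with the truth recorded in a manifest.
What these fixtures do not emulate: fMRI noise sources (motion, drift,
physiological regressors), hemodynamics, conduction delays, or realistic DTI
weight distributions. Passing recovery tests therefore show that the fitting
machinery identifies schedule parameters from FCD structure under the model's
own assumptions — not that those parameters are identifiable from real data
with preprocessing artifacts.

## Numerical conventions and limitations

- Zero-variance windows correlate as 0 (warned); constant signals make the
  analytic phase undefined and raise.
- compare_conditions maps the degenerate both-samples-constant-equal-means
  case to t = 0, p = 1.
- Schedules are evaluated in session time (t = 0 at recording start); the
  burn-in is integrated at the baseline value.
- The time axis of reactivity curves is the a_p sample grid; "t = 0" for
  baseline subtraction is the first post-injection sample.
- Known limitations: homogeneous a only; no forcing phase randomization;
  Euler (not Heun/Milstein) integration; FCD identifiability degrades for
  schedules whose transient stays far above the bifurcation (shallow λ), so
  placebo-like conditions recover λ near the grid minimum but β only weakly.
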