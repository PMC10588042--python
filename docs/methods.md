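# Methods

## Setting and model

The package plans concentration–response experiments in which a single
set of concentrations must serve the simultaneous estimation of many
curves — the motivating case being toxicogenomic microarray studies
where thousands of gene-expression responses to one compound are fitted
gene by gene, all from observations taken at the same concentrations.

Each curve is modelled by the four-parameter sigmoid Emax (Hill)
function

    eta(x, theta) = E0 + x^h * Emax / (x^h + EC50^h),

with additive i.i.d. Gaussian errors.  `E0` (response units) is the
placebo response, `Emax` (response units, negative for down-regulation)
the maximal effect, `EC50` (concentration units, in (0, infinity)) the
half-maximal concentration, and `h` (dimensionless) the Hill slope.
Evaluation uses the logistic form `E0 + Emax * expit(h*(ln x − ln
EC50))`, which is overflow-free for `h` up to 10 and `x` up to 1000
(where `x^h` itself reaches 1e30), with explicit limits at `x = 0`
(`eta = E0`, gradient `(1, 0, 0, 0)`), avoiding `0^h` and `ln 0` for
`h < 1`.

## Design theory

An approximate design `xi` is a probability measure with weights `w_i`
on support concentrations `x_i` in `[0, x_max]` (default `x_max =
1000`).  Its information matrix is `M(xi, theta) = sum_i w_i g(x_i)
g(x_i)^T` with `g` the parameter gradient of `eta`.  Local D-optimality
maximizes `psi_D = det(M)^(1/4)`; candidate optima are certified with
the general equivalence theorem: `xi` is locally D-optimal iff the
sensitivity `d(x, xi, theta) = g^T M^{-1} g − 4` is nonpositive on the
whole design space.  All certificates scan a uniform 2001-point grid on
`[0, x_max]` plus the support, with pass tolerance 1e-3 on the
sensitivity value; the grid density and tolerance are package choices
(converged results typically certify at 1e-6 or better).

For the sigmoid Emax model the locally D-optimal design is known to
have exactly four support points with equal weights 1/4, two of them
the boundary points.  `solve_local_d_optimal` therefore only searches
the two interior points (particle swarm, then Nelder–Mead polish) and
certifies the result.

A design serving `G` curves simultaneously is scored by the
prior-weighted mean of its D-efficiencies over a finite parameter
ensemble `{theta_g}` with discrete prior `pi`:

    Psi(xi, pi) = sum_g pi(theta_g) * Eff_D(xi, theta_g),
    Eff_D(xi, theta) = psi_D(xi, theta) / psi_D(xi*_theta, theta),

which lies in [0, 1], is concave in the design measure, and is
certified by the analogous simultaneous sensitivity `s(x, xi, pi) =
sum_g pi * Eff_D * d(x, xi, theta_g) <= 0`.  Standardizing through
efficiencies (rather than averaging `psi_D` itself) keeps curves with
very different information-matrix scales commensurable; `Eff_D` is
invariant to the linear parameters `(E0, Emax)`, so only the `(EC50,
h)` distribution of the ensemble matters, and local solves are cached
on `(EC50, h)`.

## Solvers

Singularity handling is scale-relative throughout: `M` counts as
singular when `det(M) <= 1e-12 * prod(diag(M))`, a relative measure by
the Hadamard bound `det <= prod(diag)` for PSD matrices.  Raw
determinant thresholds are meaningless across the dynamic range induced
by slopes between 0.05 and 10, and this particular relative form scales
exactly like the determinant when `Emax` is rescaled, so the
singular/nonsingular classification — and with it the D-efficiency — is
invariant to the linear parameters, as the theory requires.
Sensitivity evaluation on a singular matrix raises an explicit error
rather than falling back to a pseudo-inverse.

`solve_simultaneous_d_optimal` searches jointly over up to
`max_support` points (default 12; the boundary points are always
candidates since every local optimum contains them, with their weights
free) and weights mapped to the simplex through a softmax.  The search
is a seeded global-best particle swarm (constriction coefficients
w = 0.7298, c1 = c2 = 1.49618; default 40 particles, 300 iterations,
5 restarts with seeds seed+0..4).  The best particle is then polished
deterministically:

1. near-duplicate support points (within 1e-3 * x_max) are merged —
   the swarm tends to split one optimal point's mass across two
   near-coincident points;
2. weights are optimized exactly for fixed support with the
   multiplicative algorithm `w_i <- w_i * (dPsi/dw_i) / Psi`, monotone
   for this concave D-type criterion;
3. each interior support point is refined by bounded 1-D maximization
   of Psi;
4. if the simultaneous sensitivity still peaks above half the pass
   tolerance anywhere on the grid, the argmax is added as a new support
   point with weight 1e-3 and the loop repeats.

On emission, support points closer than 1e-6 * x_max are merged and
weights below 1e-4 pruned (with renormalization).  A design that still
fails the certificate raises a non-convergence error carrying the best
candidate.  The polish scheme (weight/coordinate alternation plus
sensitivity-guided point addition) was chosen over a single
high-dimensional simplex polish because it reaches certificate-level
accuracy reliably; every returned design is certified, so optimizer
hyperparameters affect runtime, never silent correctness.  With one
fixed seed the solver is bit-reproducible.

A note on the printed reference values for the seven-curve VPA
ensemble: the solver's certified optimum carries weight 0.1945 at the
upper boundary.  Cross-checking with an independent multiplicative
algorithm on a fixed 2001-point candidate grid reproduces 0.1945 to
four decimals, and the certificate maximum is 1.3e-6, so the package
reports that value as the optimum.

## K-means cluster design

Given locally optimal designs for many curves, the cluster design with
`L` conditions keeps the common support `C0` (points shared by every
design within `intersect_tol`, default 1e-6 * x_max), clusters the
remaining pooled support points — duplicates retained, so frequently
chosen concentrations weigh more — into `K = L − |C0|` groups by 1-D
k-means (scikit-learn, Euclidean distance, 10 random initializations
per repetition), repeats the clustering `J` times (default 100, for
robustness to initialization) with sub-seeds spawned from the main
seed, averages the sorted centers position by position, and assigns
equal weights `1/L`.  `L` defaults to 9, mirroring the original
VPA study layout of nine experimental-condition slots.  Unlike the
simultaneous criterion, no equivalence certificate exists for this
construction; its quality is assessed through `Psi` and simulation.

## Exact designs

`efficient_rounding` converts weights to integer replications summing
to `N` by Pukelsheim–Rieder apportionment: initialize `r_i =
ceil((N − n/2) w_i)`, then increment the index minimizing `r_j / w_j`
or decrement the index maximizing `(r_j − 1)/w_j` until the total is
`N`, ties to the lowest index.  Every support point keeps at least one
observation; `N < n` is an error.

## Simulation engine

A scenario is a design plus a total sample size `N`.  The study grid
mirrors the VPA benchmark: `N` in {18, 27, 36, 45, 63, 90}, noise
`sigma = 0.2 * |Emax|` per curve, and by default 500 simulation
replicates per scenario (tests and the shipped examples use 100 or
fewer replicates and the seven-curve representative ensemble, which
reproduce the qualitative ordering at a fraction of the cost).  For
each simulated dataset the model is refitted by least squares — equal
to maximum likelihood under Gaussian errors — with the nonlinear
parameters restricted to `EC50 in [0, 1500]`, `h in [0.05, 10]`.

The fitter profiles the linear parameters in closed form for each
candidate `(EC50, h)`, locates the basin on a 40-point multiplicative
EC50 grid crossed with a 25-point `h` grid, and refines with bounded
Nelder–Mead in `(ln EC50, h)`.  The optimizer's effective lower EC50
bound is 1e-2: `EC50 = 0` makes the curve constant and the nonlinear
parameters unidentifiable.  Grid fractions are precomputed once per
design, so one fitter serves thousands of replicates.  Noiseless data
are recovered to ~1e-8 relative error in `(EC50, h)`.

Fit quality per curve is

    RMSE(g, S)  = mean over replicates of
                  sqrt( (1/1001) * sum_{x=0..1000} (eta(x, theta_hat) − eta(x, theta_g))^2 )
    NRMSE(g, S) = RMSE(g, S) / |Emax_g|,

the RMSE grid being exactly the 1001 integer concentrations.  The
normalization uses `|Emax|` so NRMSE is nonnegative for down-regulated
curves.  Summaries report min, quartiles, median, mean and max, with an
optional variant dropping points above the upper 1.5 IQR whisker.
Noise streams are spawned per (scenario, curve) from the scenario seed:
runs are bit-reproducible and different designs see independent noise.

## Synthetic ensemble generator

`generate_parameter_ensemble` emulates the empirical joint distribution
of fitted `(EC50, h)` values observed in the VPA gene-expression data:
a 5x5 cell grid on `[0, 1000] x [0.05, 10]` in which seven cells carry
61% of the mass (split per their relative frequencies) and the rest is
uniform; draws are uniform within a cell; draws from cells whose slope
interval ends at the boundary `h = 10` land exactly on `h = 10` with
probability 0.9, reproducing the ~32% point mass of boundary slopes
seen in such fits (boundary pile-up is a real feature of constrained
fitting).  Linear parameters default to `E0 = 1`, `Emax = −1`, the
standardization under which all curves share a unit response range.
Zero-width cells give point distributions, so the seven representative
vectors themselves are a special case.  `filter_ensemble` applies the
admissibility restriction `EC50 <= 1000`, `h in [0.05, 10]` and
renormalizes the prior.

What the generator does *not* emulate: per-curve linear-parameter
variation (irrelevant to design criteria, which are invariant to it,
but it does standardize the simulated signal-to-noise ratio at
`|Emax|/sigma = 5` for every curve), correlation between genes
(curves are simulated independently), model misspecification (every
synthetic curve is exactly sigmoid Emax), and heteroscedastic or
non-Gaussian noise.  Passing simulation tests therefore demonstrate
design-quality differences under the assumed model, not robustness to
model violations.

## Known limitations

- Only D-optimality is implemented; no A-, c- or E-criteria, no
  minimax or continuous-prior Bayesian criteria.
- Only the sigmoid Emax family ships, though the design core consumes
  any function/gradient pair.
- The simultaneous solver's support budget (default 12, then pruning)
  is a heuristic; the certificate guarantees optimality of the
  returned measure, and in practice the pruned optimum for the
  reference ensemble has 9 points.
- Homoscedastic Gaussian errors per curve are assumed throughout the
  simulation engine.
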