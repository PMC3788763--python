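# Methods

`coalabc` implements likelihood-free (ABC) inference of the order and timing
of divergence among three regional mtDNA population groups — SAG (South
Amazon), NAG (North Amazon) and NC (North/Central America) — of the New World
screwworm fly, together with the simulation machinery the inference rests on.
This note records the model, the numerical choices, and what the shipped
validation experiments do and do not establish.

## Demographic model

A *scenario* is a backward-in-time event list over named populations:

- **merge** — all lineages of a source population move to a destination
  population (a forward-time population split);
- **admix** — each lineage of a target population independently moves to a
  donor population with probability equal to an admixture rate (a forward-time
  admixture pulse into the target);
- **resize** — a stepwise change of a population's effective size.

Eight scenarios ship as YAML configuration files.  Sc1–Sc3 place the oldest
split (`t_3`) between NC and the South American ancestor and the later split
(`t_2`) between NAG and SAG; Sc4–Sc6 reverse that order.  Within each triple
the scenarios differ in how the current populations reached their present
sizes: one shared expansion time (`t_exp`; Sc1/Sc4), three independent
expansion times (`t_expSAG`, `t_expNAG`, `t_expNC`; Sc2/Sc5), or size changes
coincident with the divergence events themselves (Sc3/Sc6).  Sc7 adds to Sc1 a
bidirectional NAG↔SAG pulse at `t_adm1 < t_2` with rates `ra` (SAG←NAG) and
`rb` (NAG←SAG).  Sc8 adds to Sc1 a pulse at `t_adm2` with `t_2 < t_adm2 <
t_3`, in which the South American ancestral population (then carrying both SAG
and NAG lineages) receives a fraction `rc` of its lineages from the NC branch.

The Sc8 wiring deserves a remark: an admixture "between NAG and SAG" at a time
older than their common ancestor's split is not directly expressible in a
backward-time event engine, because only the SA-ancestor and NC branches exist
in that epoch.  We model it as ancestral gene flow from the NC lineage into
the SA-ancestor, which preserves the intended signal (NC-related ancestry
inside the South American gene pool predating the NAG/SAG split) while keeping
`t_adm2` an operative event time.  The epoch-size wiring of Sc2–Sc6 (which of
the slots `N1`–`N4` applies to which population and epoch) is likewise a
modelling choice, fixed and documented in the configuration files; users can
redefine any of it by supplying their own YAML file with the same schema.

Effective sizes are effective numbers of mtDNA gene copies (maternal
lineages), used directly as haploid coalescent sizes.  No ploidy or sex-ratio
scaling is applied by default; `size_scaling` in the scenario config applies a
uniform multiplier if a different convention is wanted.  Continuous growth and
migration (as opposed to pulse admixture) are out of scope.

## Priors and constraints

Each parameter has an independent uniform prior; defaults (in the shipped
configs):

| parameter | interval | units |
|---|---|---|
| `N_anc` | [1 000, 60 000] | gene copies |
| `N_SAG` | [100 000, 3 600 000] | gene copies |
| `N_NAG` | [150 000, 800 000] | gene copies |
| `N_NC` | [40 000, 150 000] | gene copies |
| `N1`–`N4` | [100, 200 000] | gene copies (between the expansion and `t_3`) |
| `t_exp*` | [60 000, 450 000] | generations |
| `t_adm1`, `t_adm2` | [20 000, 300 000] | generations |
| `t_2` | [50 000, 350 000] | generations |
| `t_3` | [100 000, 1 000 000] | generations |
| `Mu` | [10⁻¹¹, 10⁻⁷] | substitutions/site/generation |
| `ra`, `rb`, `rc` | [0.01, 0.99] | dimensionless |

The joint prior is truncated by inequality constraints: `t_exp ≤ t_2 < t_3`
(each expansion time in the multi-expansion scenarios), `t_adm1 < t_2`,
`t_2 < t_adm2 < t_3`, `N_anc < N_NC ≤ N_NAG ≤ N_SAG`, and every epoch size
`> N_anc`.  Sampling is by exact rejection from the unconstrained joint, so
accepted draws follow the truncated distribution exactly; a property test
compares the accepted marginals against a brute-force filter oracle
(Kolmogorov–Smirnov).  The mutation-rate prior is uniform on the rate itself,
as specified; a log-uniform variant can be expressed by editing the config
(at the cost of redefining the parameter).

## Coalescent simulation

Between demographic events the populations are isolated, so each population's
coalescent runs independently: with `k` lineages in a population of haploid
size `N`, the next coalescence is exponential with rate `k(k−1)/(2N)` per
generation (continuous-time approximation; the smallest sizes under the priors
are ≥ 100, where the discrete-generation correction is negligible).  Events at
equal drawn times are applied in the order listed in the scenario file.
Simulation continues past the last event until the grand MRCA.  Validation:
`E[T₂] = N`, `E[TBL] = 2N Σ 1/i`, agreement with msprime on single-population
TMRCA distributions, admixture pulse displacement frequencies, and the
absence of cross-population coalescence before the relevant merge.

## Sequence evolution (HKY+I+Γ)

Sites are independently invariant with probability `p_invariant` (default
0.92); the rest draw a relative rate from Gamma(shape 2.0, mean 1).  Rates are
rescaled so the mean over *all* sites is one, making the scenario's `Mu` the
mean per-site substitution rate.  Invariance is per-site Bernoulli rather
than a fixed count — at L = 1752 the difference is a √L-scale fluctuation in
the invariant fraction.  The HKY rate matrix (default κ = 2.0, equal base
frequencies; both configurable, with an option to take empirical frequencies
from an observed alignment) is scaled to one expected substitution per unit
rate-time at stationarity.

Branch evolution is simulated by per-site uniformization: candidate events
arrive as a Poisson process at the dominating rate `q_max · µ · rate_s` along
each branch and each applies one step of the embedded jump chain
`I + Q/q_max`.  This draws from the exact CTMC (no time discretisation, exact
under rate heterogeneity) and costs O(expected substitutions), which for an
mtDNA-scale locus is a few hundred events per dataset.  Validation: Poisson
expectation of pairwise differences at small divergence, reduction to the
Jukes–Cantor closed form at κ = 1 with equal frequencies, transition bias at
large κ, and stationary base composition on long branches.

## Summary statistics

The ABC summary vector has the fixed order: number of haplotypes (SAG, NAG,
NC), segregating sites (×3), mean pairwise differences (×3), pairwise F_ST
for (SAG,NAG), (SAG,NC), (NAG,NC) — 12 values.  F_ST is the Hudson-type
estimator `1 − H_w/H_b` with `H_w` the unweighted mean of the two
within-population mean pairwise differences and `H_b` the between-population
mean pairwise difference; it is 0 when `H_b = 0`, and negative estimates are
kept as computed in the reference table (information for the regression;
clamping is a display concern).  Which F_ST estimator the original analysis
software used is not documented, so cross-package comparability of this one
statistic is approximate.  Haplotype identity is exact string equality
(simulated data contain no gaps or ambiguity codes).

The descriptive report adds haplotype diversity `n(1−Σp²)/(n−1)` with Nei's
sampling SD, nucleotide diversity (mean pairwise difference per site) with
Nei's total variance, and AMOVA-style pairwise Φ_ST from the matrix of
pairwise difference counts, with a label-permutation p-value
(`(1+#{perm ≥ obs})/(n_perm+1)`, or exact enumeration over all assignments
when `n_perm=None`).  Φ_ST is kept separate from the Hudson F_ST of the ABC
vector because the two serve different roles (description vs. simulation
summary).

All statistics are computed from per-column allele counts (O(nL)), and each
is verified against a pairwise-enumeration oracle on randomized alignments.

## ABC machinery

**Reference table.**  One record per prior simulation (scenario id, parameter
draw, summary vector), built from per-record generators seeded by
`(seed, scenario index, record index)`, so tables are bit-reproducible and
extendable.  CSV serialisation carries a provenance manifest.

**Rejection.**  Statistics are standardized by their reference-table standard
deviation (zero-variance statistics pass through unscaled); the `⌈fraction·n⌉`
records closest to the observed vector in Euclidean distance are retained,
ties broken by record index.  MAD standardization was considered and left out:
with count-valued statistics the SD is stable at the table sizes involved.

**Scenario choice.**  A multinomial logistic regression of scenario identity
on the standardized statistic deviations from the observed point, fitted over
the retained records by Newton iteration with a weak ridge penalty (10⁻⁶);
the fitted probabilities at zero deviation are the scenario probabilities.
95% confidence intervals use the delta method on the asymptotic covariance of
the estimator (the probabilities at the observed point depend only on the
intercepts).  Under quasi-separation — diverging coefficients, which at
desk-scale retained sets (hundreds of records) otherwise hand probability ≈ 1
to a lone separable record — the fit is repeated with a stronger penalty
(10⁻³ per record) and a warning.  The in-house fit is cross-checked against
statsmodels' MNLogit in the test suite.  Scenarios absent from the retained
set get probability 0.  The raw rejection frequencies are reported alongside.

**Parameter estimation.**  Local-linear regression adjustment with an
Epanechnikov kernel `1 − (d/δ)²` over rejection distance (δ = largest
retained distance).  Parameters are first mapped to an unbounded scale by the
logit of their position within their prior interval, the weighted linear
regression of transformed parameters on statistic deviations is evaluated at
the observed point (intercept plus residuals), and results are
back-transformed — adjusted values therefore always respect the prior bounds.
A rank-deficient design falls back to a ridge solve with a warning.  Reported
summaries per parameter: weighted mean, median, 2.5%/97.5% quantiles
(interpolated weighted ECDF), and mode (weighted Gaussian KDE, Silverman
bandwidth, 512-point grid).  The regression estimates p+1 = 13 coefficients
per parameter, so retained sets should be several times that; with a 10⁴
single-scenario table, a 5% acceptance (500 records) is a sound desk-scale
default, and the credible-interval coverage experiment uses exactly that.
Adjustment with only tens of records overfits and shrinks the intervals —
visible as under-coverage — which is a property of the method, not a failure
of the implementation.

**Model checking.**  Parameter rows are resampled from the weighted adjusted
posterior (rows violating the scenario's inequality constraints — possible
because the adjustment acts on marginals — are redrawn), pseudo-observed
datasets are simulated, and each observed statistic is located within its
posterior-predictive sample: the reported tail probability is the
midpoint-corrected predictive CDF value, with `p = 2·min(F, 1−F)` as the
two-sided summary.

**Hierarchical protocol.**  The study design compares the six divergence
scenarios first, the two admixture scenarios second, and the winners head to
head.  This is a driver recipe over `DivergenceABC` with different scenario
lists, not hard-coded behaviour.

## Time-unit conversions

Generation time `T = α + s/(1−s)` days, with maturity age α = 20 d and daily
adult survival s = 0.798 giving T = 23.95 d (full precision used internally;
display rounds to the centiday).  Generations convert to years via
`g · T / 365.25`.

## Synthetic data and what the tests show

The generator emulates the study's observed structure: 249/53/15 sampled
lineages over one combined 1752-site locus, high haplotype diversity
(≈0.95–0.99 at the preset), low nucleotide diversity (≈0.004/site), and no
haplotypes shared between NC and the South American groups in most
replicates.  The Sc1 preset (`SC1_TRUTH`) centres the demographic parameters
on the fitted posterior modes (N_SAG = 2.08×10⁶, N_NAG = 5.75×10⁵,
N_NC = 9.8×10⁴, t_exp = 110k, t_2 = 139k, t_3 = 233k generations,
N_anc = 4.9×10³); the mutation rate 1.8×10⁻⁸ was chosen once so simulated
nucleotide diversity lands near the observed magnitude rather than taken from
the very wide rate prior.  Pre-expansion epoch sizes `N1`–`N4` (50k, 30k,
20k, 10k) are a choice within the constraint `N_k > N_anc`, since the fitted
analysis does not report them.

The generator does not attempt the real data's haplotype-network topology,
the island groups, or the 230-haplotype composition; passing tests establish
that the machinery is correct and calibrated on data of the study's shape and
scale, not that the original point estimates are recovered from real
sequences.

## Validation experiment sizes

The simulation-heavy experiments run at a desk scale chosen once: three
populations of 50/30/15 sampled lineages, an 800-site locus, 10⁴ prior
simulations per scenario (the study-scale 10⁶ per scenario at 249/53/15 ×
1752 sites is a configuration choice away, not a code path difference).
Under those conditions:

- rejection with fraction 1 returns the constrained prior (KS, n = 10⁴);
- pseudo-observed data from Sc1 with well-separated parameters (one strong
  recent expansion, deep splits) rank Sc1 first in ≥ a majority of 20
  replicate analyses against all six divergence scenarios (observed: 20/20);
- 95% credible intervals for `t_3` cover prior-drawn truths in ≥ 85 of 100
  analyses (observed: 97/100 at a 5% acceptance of a 10⁴-record table).

The study-scale headline numbers (posterior probability 0.8251 for the best
scenario, the fitted time posteriors) depend on the real GenBank sequences
and 10⁶–10⁷ simulations and are deliberately not asserted anywhere; the
package reproduces the *procedure* and validates it on synthetic ground
truth.

## Known limitations

- Single locus, no recombination, no migration other than pulse admixture,
  no serial sampling, no indels or ambiguity codes.
- The multinomial-logistic confidence intervals are asymptotic; at very small
  retained counts they are optimistic.
- The Φ_ST permutation test permutes individuals between two groups only
  (pairwise design, as in the descriptive tables); a full multi-group AMOVA
  is out of scope.
- Scenario configs express stepwise sizes only; exponential growth is not
  representable.
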