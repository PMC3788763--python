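# coalabc

Approximate Bayesian computation (ABC) for choosing among demographic
divergence scenarios and estimating their parameters from multi-population
mtDNA haplotype data.

`coalabc` was built around a concrete inference problem: three regional
populations of the New World screwworm fly (*Cochliomyia hominivorax*) — the
South Amazon group (SAG), North Amazon group (NAG) and North/Central America
group (NC) — sampled for a combined 1752-bp mitochondrial fragment, with
competing hypotheses about the order and timing of their divergence, their
expansions, and possible admixture.  Everything is general over user-defined
scenarios, sample sizes and loci; the study design ships as defaults.

The package provides:

- a **structured-coalescent simulator** for scenarios built from population
  splits, admixture pulses and stepwise size changes, with named parameters
  under uniform priors truncated by inequality constraints
  (e.g. `t_exp ≤ t_2 < t_3`, `N_anc < N_NC ≤ N_NAG ≤ N_SAG`);
- **HKY+I+Γ sequence evolution** along the simulated genealogies
  (default 92% invariant sites, gamma shape 2);
- the classic **12-statistic summary vector** (per-population haplotype
  counts, segregating sites, mean pairwise differences; pairwise Hudson
  F_ST), plus descriptive diversity tables (Ĥ ± SD, π ± SD, AMOVA-style
  Φ_ST with permutation p-values);
- **rejection ABC** with multinomial-logistic **scenario choice**
  (delta-method 95% confidence intervals) and local-linear-regression
  **parameter estimation** with a logit transform over the prior bounds,
  Epanechnikov kernel weights, and posterior summaries
  (mean/median/mode/2.5%/97.5%);
- posterior-predictive **model checking**;
- a **synthetic-data generator** producing study-shaped pseudo-observed
  datasets (FASTA + population map + ground-truth record).

## The model in brief

A scenario is a backward-time event list over populations.  Lineages within a
population of haploid size N coalesce at rate k(k−1)/(2N); a split is a merge
of lineage pools, an admixture pulse moves each target lineage to the donor
with probability r.  Sequences evolve under HKY with per-site gamma rates and
an invariant-site fraction; datasets are summarised by the 12-vector s.
Given observed s_obs, scenarios M₁…M_k with priors π(θ|M), ABC approximates

    P(M | s_obs)  and  p(θ | M, s_obs)

by simulating (M, θ, s) from the prior, keeping the simulations with s
closest to s_obs, regressing scenario identity (multinomial logit) and
parameters (local-linear, logit-transformed) on the standardized deviations
s − s_obs, and evaluating at s_obs.  Split times in generations convert to
years through the insect's generation time T = α + s/(1−s) = 23.95 days
(maturity α = 20 d, daily adult survival s = 0.798).

## Worked example

Simulate a pseudo-observed dataset under scenario Sc1 (NC splits first, then
NAG/SAG, one strong shared expansion afterwards), then infer scenario and
parameters from scratch:

```python
import coalabc as ca
from coalabc.synthetic import StudyTemplate

truth = {
    "N_anc": 1500.0, "N_SAG": 2.0e6, "N_NAG": 6.0e5, "N_NC": 1.0e5,
    "N1": 4000.0, "N2": 3000.0, "N3": 2500.0, "N4": 3000.0,
    "t_exp": 65_000.0, "t_2": 300_000.0, "t_3": 650_000.0, "Mu": 2e-8,
}
template = StudyTemplate(
    sample_config=ca.SampleConfig((("SAG", 50), ("NAG", 30), ("NC", 15)), 800)
)
aln, _ = ca.generate_pseudo_observed("Sc1", params=truth, template=template, seed=7)

model = ca.DivergenceABC(aln, scenarios=("Sc1", "Sc2", "Sc3", "Sc4", "Sc5", "Sc6"))
model.simulate(n_per_scenario=3000, seed=11)
res = model.fit(fraction=0.02, param_fraction=0.25)
print(res.summary())
```

Output (abridged):

```
Scenario probabilities (logistic regression):
  Sc1   P = 0.4271 [0.2013, 0.6528] (direct 0.2333) <- best
  Sc2   P = 0.3531 [0.0811, 0.6250] (direct 0.2361)
  Sc3   P = 0.0472 [0.0000, 0.1600] (direct 0.0028)
  Sc4   P = 0.0745 [0.0000, 0.1662] (direct 0.2833)
  Sc5   P = 0.0467 [0.0000, 0.1058] (direct 0.2389)
  Sc6   P = 0.0515 [0.0000, 0.1635] (direct 0.0056)

Posterior parameter estimates under Sc1:
  parameter             mean      median        mode        q025        q975
  ...
  t_2              2.696e+05   2.782e+05    3.13e+05   1.392e+05   3.451e+05
  t_3              6.837e+05   6.888e+05   7.538e+05    3.74e+05   9.688e+05
  t_exp            8.274e+04   7.644e+04   6.919e+04   6.072e+04   1.334e+05
  t_2_years        1.768e+04   1.824e+04   2.053e+04        9125   2.263e+04
  t_3_years        4.483e+04   4.516e+04   4.943e+04   2.453e+04   6.352e+04
```

The true scenario receives the highest probability; its close competitor Sc2
(independent expansion times per population) nests Sc1, so some posterior
mass there is expected.  Every true parameter — t_2 = 3×10⁵, t_3 = 6.5×10⁵,
t_exp = 6.5×10⁴ generations — lies inside its 95% credible interval, and the
`*_years` rows convert the time parameters through the 23.95-day generation
time.  A posterior-predictive check is one call away:
`res.model_check(n_pod=1000, seed=3)`.

## Command line

```bash
coalabc scenario list                 # the eight shipped scenarios
coalabc scenario show Sc7             # events, priors, constraints
coalabc scenario validate my.yaml     # check a user scenario config
coalabc synth generate --scenario Sc1 --preset --seed 42 --out data/
coalabc sumstats data/dataset.fasta data/popmap.tsv
coalabc abc simulate --scenarios Sc1,Sc2,Sc3 --n 10000 --seed 1 --out table.csv
coalabc abc fit data/dataset.fasta data/popmap.tsv --table table.csv --out fit.json
coalabc abc check data/dataset.fasta data/popmap.tsv --table table.csv
```

Observed data enter as a FASTA alignment of {A,C,G,T} haplotype sequences
plus a two-column (individual, population) tab-separated map.  Scenario
configurations are YAML files with a versioned schema (see
`src/coalabc/configs/`); user files with the same schema plug in anywhere a
scenario id is accepted.

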