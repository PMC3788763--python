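"""Rejection/regression ABC: reference tables, scenario choice, parameter
estimation, and posterior-predictive model checking.

The reference table holds one record per prior simulation: the scenario
identity, the parameter draw, and the 12-statistic summary vector.  Model
choice fits a multinomial logistic regression of scenario identity on
standardized summary-statistic deviations from the observed vector among the
retained (closest) simulations and reads the fitted probabilities at the
observed point, with delta-method confidence intervals from the asymptotic
covariance of the maximum-likelihood estimator.  Parameter estimation uses
the classic local-linear regression adjustment with an Epanechnikov kernel
after a logit transformation of each parameter over its prior bounds, so
adjusted values always respect the prior support.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from math import ceil
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import gaussian_kde

from .coalescent import SampleConfig, simulate_genealogy
from .mutation import SubstitutionSettings, evolve_alignment
from .scenarios import ParameterDraw, ScenarioSpec, sample_prior_draw
from .sumstats import SUMMARY_STAT_NAMES, summary_vector

__all__ = [
    "ReferenceTable",
    "Selection",
    "ModelChoiceResult",
    "PosteriorSample",
    "ModelCheckReport",
    "build_reference_table",
    "rejection_select",
    "model_choice",
    "estimate_parameters",
    "model_check",
    "simulate_record",
]


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------


@dataclass
class ReferenceTable:
    """Bank of (scenario, parameter draw, summary vector) records."""

    data: pd.DataFrame
    stat_names: Tuple[str, ...] = SUMMARY_STAT_NAMES
    provenance: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [s for s in self.stat_names if s not in self.data.columns]
        if missing:
            raise ValueError(f"reference table is missing statistic columns: {missing}")
        if "scenario" not in self.data.columns:
            raise ValueError("reference table needs a 'scenario' column")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def scenarios(self) -> List[str]:
        return sorted(self.data["scenario"].unique())

    def scenario_counts(self) -> pd.Series:
        return self.data["scenario"].value_counts().sort_index()

    def stat_matrix(self) -> np.ndarray:
        return self.data.loc[:, list(self.stat_names)].to_numpy(dtype=float)

    def stat_std(self) -> np.ndarray:
        """Per-statistic standard deviation; zero-variance statistics get 1
        so they contribute their raw deviation."""
        sd = self.stat_matrix().std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        return sd

    def restrict(self, scenario: str) -> "ReferenceTable":
        sub = self.data[self.data["scenario"] == scenario].reset_index(drop=True)
        if sub.empty:
            raise ValueError(f"no records for scenario {scenario!r}")
        return ReferenceTable(sub, self.stat_names, dict(self.provenance))

    def append(self, other: "ReferenceTable") -> "ReferenceTable":
        if other.stat_names != self.stat_names:
            raise ValueError("cannot append tables with different statistics")
        return ReferenceTable(
            pd.concat([self.data, other.data], ignore_index=True),
            self.stat_names,
            {**self.provenance, "appended": True},
        )

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# coalabc-reference-table-v1\n")
            fh.write("# " + json.dumps(self.provenance, sort_keys=True) + "\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        provenance: Dict = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            if not line.startswith("# coalabc-reference-table"):
                fh.seek(pos)
            else:
                manifest = fh.readline()
                if manifest.startswith("# "):
                    provenance = json.loads(manifest[2:])
                else:
                    fh.seek(fh.tell() - len(manifest))
            data = pd.read_csv(fh)
        return cls(data, provenance=provenance)


def simulate_record(
    spec: ScenarioSpec,
    cfg: SampleConfig,
    settings: SubstitutionSettings,
    rng: np.random.Generator,
    draw: Optional[ParameterDraw] = None,
) -> Tuple[ParameterDraw, np.ndarray]:
    """One prior simulation: draw (unless given) -> genealogy -> alignment ->
    summary vector."""
    if draw is None:
        draw = sample_prior_draw(spec, rng)
    g = simulate_genealogy(spec, draw, cfg, rng, check_draw=False)
    aln = evolve_alignment(g, cfg.locus_length, settings, rng, mu=draw["Mu"])
    pops = [p for p, n in cfg.sample_sizes if n >= 2]
    stats = summary_vector(aln, populations=tuple(pops))
    return draw, stats


def build_reference_table(
    specs: Sequence[ScenarioSpec],
    n_per_scenario: int,
    cfg: SampleConfig,
    seed: int,
    settings: Optional[SubstitutionSettings] = None,
    progress: bool = False,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` prior datasets per scenario.

    Each record uses an independent generator derived from ``(seed, scenario
    index, record index)``, so tables are reproducible and can be extended by
    appending records with higher indices.
    """
    if n_per_scenario < 1:
        raise ValueError("n_per_scenario must be >= 1")
    if settings is None:
        settings = SubstitutionSettings()
    param_names: List[str] = []
    for spec in specs:
        for p in spec.parameter_names():
            if p not in param_names:
                param_names.append(p)

    rows = []
    for s_idx, spec in enumerate(specs):
        for i in range(n_per_scenario):
            rng = np.random.default_rng([seed, s_idx, i])
            try:
                draw, stats = simulate_record(spec, cfg, settings, rng)
            except Exception as exc:
                raise RuntimeError(
                    f"simulation failed for scenario {spec.id}, record {i} "
                    f"(seed {seed}): {exc}"
                ) from exc
            row: Dict[str, float] = {"scenario": spec.id}
            for p in param_names:
                row[p] = draw.get(p, np.nan)
            for name, value in zip(SUMMARY_STAT_NAMES, stats):
                row[name] = value
            rows.append(row)
        if progress:  # pragma: no cover - cosmetic
            print(f"  {spec.id}: {n_per_scenario} records")
    data = pd.DataFrame(rows)
    return ReferenceTable(
        data,
        provenance={
            "seed": seed,
            "n_per_scenario": n_per_scenario,
            "scenarios": [s.id for s in specs],
            "sample_sizes": dict(cfg.sample_sizes),
            "locus_length": cfg.locus_length,
        },
    )


# ---------------------------------------------------------------------------
# Rejection
# ---------------------------------------------------------------------------


@dataclass
class Selection:
    """Outcome of the rejection step: retained record indices and distances."""

    indices: np.ndarray
    distances: np.ndarray  # distance per retained record, ascending
    threshold: float  # largest retained distance (kernel bandwidth)
    fraction: float

    def __len__(self) -> int:
        return len(self.indices)


def rejection_select(
    observed: np.ndarray, table: ReferenceTable, fraction: float
) -> Selection:
    """Retain the ``ceil(fraction * n)`` records closest to the observed
    vector in standardized Euclidean distance (statistics scaled by their
    reference-table standard deviation).  Ties beyond the cutoff are broken
    by record index."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if len(table) == 0:
        raise ValueError("reference table is empty")
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (len(table.stat_names),):
        raise ValueError(
            f"observed vector has shape {observed.shape}; expected ({len(table.stat_names)},)"
        )
    sd = table.stat_std()
    z = table.stat_matrix() / sd
    z_obs = observed / sd
    dist = np.sqrt(((z - z_obs) ** 2).sum(axis=1))
    n_keep = ceil(fraction * len(table))
    order = np.argsort(dist, kind="stable")[:n_keep]
    return Selection(
        indices=order,
        distances=dist[order],
        threshold=float(dist[order].max()),
        fraction=fraction,
    )


# ---------------------------------------------------------------------------
# Multinomial logistic model choice
# ---------------------------------------------------------------------------


@dataclass
class ModelChoiceResult:
    """Posterior scenario probabilities with 95% confidence intervals."""

    scenarios: List[str]
    probabilities: np.ndarray
    conf_int: np.ndarray  # (k, 2)
    direct: np.ndarray  # rejection-frequency estimate
    n_selected: int
    counts: Dict[str, int]

    @property
    def best(self) -> str:
        return self.scenarios[int(np.argmax(self.probabilities))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": self.scenarios,
                "probability": self.probabilities,
                "ci_low": self.conf_int[:, 0],
                "ci_high": self.conf_int[:, 1],
                "direct_frequency": self.direct,
            }
        ).set_index("scenario")


def _fit_multinomial_logit(
    x: np.ndarray, y: np.ndarray, n_classes: int, ridge: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Newton fit of a (weakly ridge-penalised) multinomial logit with class 0
    as baseline.  Returns ``(theta, cov)`` where theta has shape
    ``(n_classes-1, p+1)`` (intercept first) and ``cov`` is the inverse of the
    penalised observed information, ordered class-major."""
    n, p = x.shape
    design = np.hstack([np.ones((n, 1)), x])
    d = p + 1
    k1 = n_classes - 1
    theta = np.zeros((k1, d))
    y_onehot = np.zeros((n, n_classes))
    y_onehot[np.arange(n), y] = 1.0

    for _ in range(200):
        eta = np.hstack([np.zeros((n, 1)), design @ theta.T])
        eta -= eta.max(axis=1, keepdims=True)
        prob = np.exp(eta)
        prob /= prob.sum(axis=1, keepdims=True)
        grad = design.T @ (prob[:, 1:] - y_onehot[:, 1:])  # (d, k1)
        grad = grad.T.reshape(-1) + ridge * theta.reshape(-1)
        # observed information, block (a,b) = X^T diag(p_a (delta_ab - p_b)) X
        hess = np.empty((k1 * d, k1 * d))
        for a in range(k1):
            for b in range(a, k1):
                w = prob[:, a + 1] * ((1.0 if a == b else 0.0) - prob[:, b + 1])
                block = design.T @ (design * w[:, None])
                hess[a * d : (a + 1) * d, b * d : (b + 1) * d] = block
                if a != b:
                    hess[b * d : (b + 1) * d, a * d : (a + 1) * d] = block
        hess[np.diag_indices_from(hess)] += ridge
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        theta = theta - step.reshape(k1, d)
        if np.abs(step).max() < 1e-10:
            break
    # final information for the covariance
    eta = np.hstack([np.zeros((n, 1)), design @ theta.T])
    eta -= eta.max(axis=1, keepdims=True)
    prob = np.exp(eta)
    prob /= prob.sum(axis=1, keepdims=True)
    hess = np.empty((k1 * d, k1 * d))
    for a in range(k1):
        for b in range(a, k1):
            w = prob[:, a + 1] * ((1.0 if a == b else 0.0) - prob[:, b + 1])
            block = design.T @ (design * w[:, None])
            hess[a * d : (a + 1) * d, b * d : (b + 1) * d] = block
            if a != b:
                hess[b * d : (b + 1) * d, a * d : (a + 1) * d] = block
    hess[np.diag_indices_from(hess)] += ridge
    cov = np.linalg.pinv(hess)
    return theta, cov


def model_choice(
    selection: Selection,
    observed: np.ndarray,
    table: ReferenceTable,
    ridge: float = 1e-6,
) -> ModelChoiceResult:
    """Logistic-regression estimate of per-scenario posterior probabilities.

    A multinomial logistic regression of scenario identity on standardized
    summary-statistic deviations from the observed point is fitted over the
    retained simulations; the fitted probabilities at zero deviation are the
    scenario probabilities.  95% confidence intervals come from the delta
    method on the asymptotic covariance of the estimator.  Scenarios present
    in the table but absent from the selection receive probability zero.
    The weak ridge penalty keeps the fit defined under complete separation.
    """
    all_scenarios = table.scenarios
    sub = table.data.iloc[selection.indices]
    present = sorted(sub["scenario"].unique())
    counts = {s: int((sub["scenario"] == s).sum()) for s in all_scenarios}
    n_sel = len(selection)
    direct = np.array([counts[s] / n_sel for s in all_scenarios])

    probs = np.zeros(len(all_scenarios))
    ci = np.zeros((len(all_scenarios), 2))

    if len(present) == 1:
        i = all_scenarios.index(present[0])
        probs[i] = 1.0
        ci[i] = (1.0, 1.0)
        return ModelChoiceResult(all_scenarios, probs, ci, direct, n_sel, counts)

    sd = table.stat_std()
    z = table.stat_matrix()[selection.indices] / sd
    x = z - np.asarray(observed, dtype=float) / sd
    code = {s: j for j, s in enumerate(present)}
    y = sub["scenario"].map(code).to_numpy()

    theta, cov = _fit_multinomial_logit(x, y, len(present), ridge)
    if np.abs(theta).max() > 30.0:
        # (quasi-)complete separation: coefficients diverge and the fitted
        # probability at the observed point degenerates; refit with a
        # stronger (still weak per-record) penalty
        warnings.warn(
            "quasi-separation in scenario logistic regression; "
            "refitting with a stronger ridge penalty",
            RuntimeWarning,
        )
        theta, cov = _fit_multinomial_logit(
            x, y, len(present), max(ridge, 1e-3 * len(y))
        )
    k1 = len(present) - 1
    d = x.shape[1] + 1
    intercepts = theta[:, 0]
    eta = np.concatenate([[0.0], intercepts])
    eta -= eta.max()
    p_hat = np.exp(eta)
    p_hat /= p_hat.sum()

    # delta method: probabilities at x = 0 depend only on the intercepts
    idx_int = np.arange(k1) * d  # positions of intercepts in the flat params
    cov_int = cov[np.ix_(idx_int, idx_int)]
    grad = np.zeros((len(present), k1))  # d p_a / d intercept_b, b indexes class a+1
    for a in range(len(present)):
        for b in range(k1):
            grad[a, b] = p_hat[a] * ((1.0 if a == b + 1 else 0.0) - p_hat[b + 1])
    var = np.einsum("ab,bc,ac->a", grad, cov_int, grad)
    se = np.sqrt(np.clip(var, 0.0, None))

    for j, s in enumerate(present):
        i = all_scenarios.index(s)
        probs[i] = p_hat[j]
        ci[i] = (max(0.0, p_hat[j] - 1.96 * se[j]), min(1.0, p_hat[j] + 1.96 * se[j]))
    # numerical guard: renormalise tiny drift
    total = probs.sum()
    if total > 0:
        probs /= total
    return ModelChoiceResult(all_scenarios, probs, ci, direct, n_sel, counts)


# ---------------------------------------------------------------------------
# Local-linear regression parameter estimation
# ---------------------------------------------------------------------------


@dataclass
class PosteriorSample:
    """Weighted, regression-adjusted posterior sample for one scenario."""

    scenario: str
    parameters: List[str]
    raw: pd.DataFrame  # accepted draws (prior scale)
    adjusted: pd.DataFrame  # regression-adjusted draws (prior scale)
    weights: np.ndarray  # Epanechnikov kernel weights, >= 0
    summaries: pd.DataFrame  # mean, median, mode, q025, q975 per parameter

    def sample_rows(self, n: int, rng: np.random.Generator) -> pd.DataFrame:
        """Resample adjusted parameter rows proportionally to the weights."""
        w = self.weights / self.weights.sum()
        idx = rng.choice(len(self.adjusted), size=n, replace=True, p=w)
        return self.adjusted.iloc[idx].reset_index(drop=True)


def _weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return float(np.interp(q, cw, v))


def _weighted_mode(values: np.ndarray, weights: np.ndarray) -> float:
    if np.ptp(values) == 0:
        return float(values[0])
    try:
        kde = gaussian_kde(values, bw_method="silverman", weights=weights)
    except np.linalg.LinAlgError:
        return float(np.average(values, weights=weights))
    grid = np.linspace(values.min(), values.max(), 512)
    return float(grid[np.argmax(kde(grid))])


def estimate_parameters(
    selection: Selection,
    observed: np.ndarray,
    spec: ScenarioSpec,
    table: ReferenceTable,
) -> PosteriorSample:
    """Local-linear regression-adjusted posterior for ``spec``'s parameters.

    All retained records must come from the target scenario (restrict the
    table first).  Parameters are logit-transformed over their prior bounds,
    regressed on standardized statistic deviations with Epanechnikov kernel
    weights over rejection distance, intercept-plus-residuals are
    back-transformed, and weighted summaries are reported.
    """
    if len(selection) == 0:
        raise ValueError("empty selection")
    sub = table.data.iloc[selection.indices]
    others = set(sub["scenario"].unique()) - {spec.id}
    if others:
        raise ValueError(
            f"selection contains records from scenarios {sorted(others)}; "
            f"restrict the table to {spec.id} before estimating parameters"
        )
    params = spec.parameter_names()
    raw = sub.loc[:, params].reset_index(drop=True)

    # Epanechnikov kernel over rejection distance
    delta = selection.threshold
    if delta > 0:
        w = 1.0 - (selection.distances / delta) ** 2
    else:
        w = np.ones(len(selection))
    w = np.clip(w, 0.0, None)
    if w.sum() == 0:  # all retained at the boundary: fall back to uniform
        w = np.ones(len(selection))

    # logit transform over prior bounds
    eps = 1e-12
    z = np.empty((len(raw), len(params)))
    bounds = []
    for j, p in enumerate(params):
        low, high = spec.priors.bounds(p)
        bounds.append((low, high))
        u = (raw[p].to_numpy(dtype=float) - low) / (high - low)
        z[:, j] = logit(np.clip(u, eps, 1.0 - eps))

    sd = table.stat_std()
    x = (table.stat_matrix()[selection.indices] - np.asarray(observed, dtype=float)) / sd

    design = np.hstack([np.ones((len(raw), 1)), x])
    sw = np.sqrt(w)
    a_w = design * sw[:, None]
    z_w = z * sw[:, None]
    beta, _, rank, _ = np.linalg.lstsq(a_w, z_w, rcond=None)
    if rank < design.shape[1]:
        warnings.warn(
            "singular local-linear design; using ridge-regularized solve",
            RuntimeWarning,
        )
        lam = 1e-8
        gram = a_w.T @ a_w + lam * np.eye(design.shape[1])
        beta = np.linalg.solve(gram, a_w.T @ z_w)

    z_adj = z - x @ beta[1:, :]  # intercept + residuals, evaluated at x = 0
    adj = np.empty_like(z_adj)
    for j, (low, high) in enumerate(bounds):
        adj[:, j] = low + (high - low) * expit(z_adj[:, j])
    adjusted = pd.DataFrame(adj, columns=params)

    rows = []
    for j, p in enumerate(params):
        v = adj[:, j]
        rows.append(
            {
                "parameter": p,
                "mean": float(np.average(v, weights=w)),
                "median": _weighted_quantile(v, w, 0.5),
                "mode": _weighted_mode(v, w),
                "q025": _weighted_quantile(v, w, 0.025),
                "q975": _weighted_quantile(v, w, 0.975),
            }
        )
    summaries = pd.DataFrame(rows).set_index("parameter")
    return PosteriorSample(spec.id, params, raw, adjusted, w, summaries)


# ---------------------------------------------------------------------------
# Posterior-predictive model checking
# ---------------------------------------------------------------------------


@dataclass
class ModelCheckReport:
    """Posterior-predictive tail probabilities per summary statistic.

    ``tail_prob`` is the predictive CDF value of the observed statistic
    (midpoint-corrected for ties); values near 0 or 1 flag statistics the
    fitted scenario fails to reproduce.  ``p_two_sided = 2 min(F, 1-F)``.
    """

    table: pd.DataFrame
    n_pod: int

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_two_sided"] < alpha]


def model_check(
    spec: ScenarioSpec,
    posterior: PosteriorSample,
    observed: np.ndarray,
    cfg: SampleConfig,
    n_pod: int,
    seed: int,
    settings: Optional[SubstitutionSettings] = None,
    max_attempts_per_pod: int = 100,
) -> ModelCheckReport:
    """Simulate ``n_pod`` pseudo-observed datasets with parameters drawn from
    the weighted posterior and locate each observed statistic within the
    posterior-predictive distribution.

    Adjusted posterior rows occasionally violate the scenario's inequality
    constraints (the regression adjusts marginals independently); such rows
    are rejected and redrawn.
    """
    if n_pod < 1:
        raise ValueError("n_pod must be >= 1")
    if settings is None:
        settings = SubstitutionSettings()
    rng = np.random.default_rng(seed)
    w = posterior.weights / posterior.weights.sum()
    stats = np.empty((n_pod, len(SUMMARY_STAT_NAMES)))
    for i in range(n_pod):
        for _ in range(max_attempts_per_pod):
            row = posterior.adjusted.iloc[int(rng.choice(len(w), p=w))]
            draw = {p: float(row[p]) for p in posterior.parameters}
            if spec.constraints.satisfied(draw):
                break
        else:
            raise RuntimeError(
                "could not draw a constraint-satisfying posterior sample; "
                "the adjusted posterior may be concentrated outside the prior support"
            )
        g = simulate_genealogy(spec, draw, cfg, rng, check_draw=False)
        aln = evolve_alignment(g, cfg.locus_length, settings, rng, mu=draw["Mu"])
        pops = [p for p, n in cfg.sample_sizes if n >= 2]
        stats[i] = summary_vector(aln, populations=tuple(pops))

    observed = np.asarray(observed, dtype=float)
    below = (stats < observed).mean(axis=0)
    equal = (stats == observed).mean(axis=0)
    tail = below + 0.5 * equal
    rows = pd.DataFrame(
        {
            "statistic": list(SUMMARY_STAT_NAMES),
            "observed": observed,
            "predictive_mean": stats.mean(axis=0),
            "predictive_sd": stats.std(axis=0, ddof=0),
            "tail_prob": tail,
            "p_two_sided": 2.0 * np.minimum(tail, 1.0 - tail),
        }
    ).set_index("statistic")
    return ModelCheckReport(rows, n_pod)
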