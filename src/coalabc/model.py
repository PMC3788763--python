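"""Model/Results surface for the full ABC analysis.

:class:`DivergenceABC` wraps an observed labelled haplotype alignment plus a
set of competing demographic scenarios; ``simulate`` builds the reference
table and ``fit`` performs rejection, logistic-regression scenario choice and
local-linear-regression parameter estimation, returning a
:class:`DivergenceABCResults` with a ``summary()`` table and a
posterior-predictive ``model_check``.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .abc_core import (
    ModelCheckReport,
    ModelChoiceResult,
    PosteriorSample,
    ReferenceTable,
    build_reference_table,
    estimate_parameters,
    model_check,
    model_choice,
    rejection_select,
)
from .coalescent import SampleConfig
from .mutation import SubstitutionSettings
from .popdata import HaplotypeAlignment, read_alignment
from .scenarios import (
    LifeHistory,
    ScenarioSpec,
    SCENARIO_IDS,
    build_scenario,
    generations_to_years,
)
from .sumstats import SUMMARY_STAT_NAMES, summary_vector

__all__ = ["DivergenceABC", "DivergenceABCResults", "hierarchical_fit"]


class DivergenceABC:
    """ABC scenario choice and parameter estimation for a labelled alignment.

    Parameters
    ----------
    alignment
        Observed haplotype alignment with population labels covering the
        scenarios' sampled populations.
    scenarios
        Scenario identifiers or :class:`ScenarioSpec` objects to compare.
        Defaults to the six divergence-without-admixture scenarios
        (``Sc1``-``Sc6``); the two admixture scenarios and hierarchical
        protocols are composed by the user from the same pieces.
    settings
        Substitution-model settings used for all simulations.
    life_history
        Used by results to convert time parameters into years.

    Examples
    --------
    >>> model = DivergenceABC.from_files("data.fasta", "popmap.tsv")
    >>> table = model.simulate(n_per_scenario=5000, seed=7)
    >>> res = model.fit(fraction=0.01)
    >>> print(res.summary())
    """

    def __init__(
        self,
        alignment: HaplotypeAlignment,
        scenarios: Optional[Sequence[str | ScenarioSpec]] = None,
        settings: Optional[SubstitutionSettings] = None,
        life_history: Optional[LifeHistory] = None,
        populations: Sequence[str] = ("SAG", "NAG", "NC"),
    ):
        self.alignment = alignment
        self.populations = tuple(populations)
        if scenarios is None:
            scenarios = SCENARIO_IDS[:6]
        self.scenarios: List[ScenarioSpec] = [
            s if isinstance(s, ScenarioSpec) else build_scenario(s) for s in scenarios
        ]
        ids = [s.id for s in self.scenarios]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate scenario ids: {ids}")
        self.settings = settings if settings is not None else SubstitutionSettings()
        self.life_history = life_history if life_history is not None else LifeHistory()

        counts = {p: len(alignment.rows_for(p)) for p in self.populations}
        missing = [p for p, n in counts.items() if n < 2]
        if missing:
            raise ValueError(
                f"populations {missing} have fewer than 2 sequences in the alignment"
            )
        self.sample_config = SampleConfig(
            tuple(counts.items()), locus_length=alignment.length
        )
        self.observed = summary_vector(alignment, populations=self.populations)
        self.table: Optional[ReferenceTable] = None

    @classmethod
    def from_files(cls, fasta_path, popmap_path, **kwargs) -> "DivergenceABC":
        """Build the model from a FASTA alignment and a population map file."""
        return cls(read_alignment(fasta_path, popmap_path), **kwargs)

    # ------------------------------------------------------------------

    def simulate(
        self, n_per_scenario: int, seed: int, progress: bool = False
    ) -> ReferenceTable:
        """Build (and cache) the prior reference table."""
        self.table = build_reference_table(
            self.scenarios,
            n_per_scenario,
            self.sample_config,
            seed,
            settings=self.settings,
            progress=progress,
        )
        return self.table

    def fit(
        self,
        table: Optional[ReferenceTable] = None,
        fraction: float = 0.01,
        param_fraction: Optional[float] = None,
        scenario: str = "best",
    ) -> "DivergenceABCResults":
        """Rejection + scenario choice + parameter estimation.

        Parameters
        ----------
        table
            Reference table; defaults to the one built by :meth:`simulate`.
        fraction
            Fraction of closest simulations retained for scenario choice.
        param_fraction
            Fraction retained (within the chosen scenario's records) for
            parameter estimation; defaults to ``fraction``.
        scenario
            ``"best"`` to estimate parameters under the highest-probability
            scenario, or an explicit scenario id, or ``None`` to skip
            parameter estimation.
        """
        if table is None:
            table = self.table
        if table is None:
            raise ValueError("no reference table; call simulate() or pass table=")
        if param_fraction is None:
            param_fraction = fraction

        selection = rejection_select(self.observed, table, fraction)
        choice = model_choice(selection, self.observed, table)

        posterior = None
        target_spec = None
        if scenario is not None:
            target = choice.best if scenario == "best" else scenario
            target_spec = next((s for s in self.scenarios if s.id == target), None)
            if target_spec is None:
                raise ValueError(f"scenario {target!r} is not part of this model")
            sub_table = table.restrict(target)
            sub_sel = rejection_select(self.observed, sub_table, param_fraction)
            posterior = estimate_parameters(sub_sel, self.observed, target_spec, sub_table)

        return DivergenceABCResults(self, table, selection, choice, posterior, target_spec)


def hierarchical_fit(
    alignment: HaplotypeAlignment,
    n_per_scenario: int,
    seed: int,
    fraction: float = 0.01,
    param_fraction: Optional[float] = None,
    final_n_per_scenario: Optional[int] = None,
    **model_kwargs,
) -> Dict[str, "DivergenceABCResults"]:
    """Three-stage hierarchical scenario comparison.

    Stage ``divergence`` compares the six divergence-without-admixture
    scenarios (Sc1-Sc6); stage ``admixture`` compares the two admixture
    scenarios (Sc7, Sc8); stage ``final`` pits the two stage winners against
    each other with a fresh (optionally larger) reference table and carries
    the parameter estimation for the overall winner.  Each stage simulates
    its own reference table — simulations are not reused across stages.

    Returns a dict with the three :class:`DivergenceABCResults`.
    """
    if final_n_per_scenario is None:
        final_n_per_scenario = n_per_scenario
    out: Dict[str, DivergenceABCResults] = {}

    stage1 = DivergenceABC(alignment, scenarios=SCENARIO_IDS[:6], **model_kwargs)
    stage1.simulate(n_per_scenario, seed=seed)
    out["divergence"] = stage1.fit(fraction=fraction, param_fraction=param_fraction)

    stage2 = DivergenceABC(alignment, scenarios=SCENARIO_IDS[6:], **model_kwargs)
    stage2.simulate(n_per_scenario, seed=seed + 1)
    out["admixture"] = stage2.fit(fraction=fraction, param_fraction=param_fraction)

    finalists = [out["divergence"].best_scenario, out["admixture"].best_scenario]
    stage3 = DivergenceABC(alignment, scenarios=finalists, **model_kwargs)
    stage3.simulate(final_n_per_scenario, seed=seed + 2)
    out["final"] = stage3.fit(fraction=fraction, param_fraction=param_fraction)
    return out


class DivergenceABCResults:
    """Fitted ABC results: scenario probabilities and posterior summaries."""

    def __init__(
        self,
        model: DivergenceABC,
        table: ReferenceTable,
        selection,
        choice: ModelChoiceResult,
        posterior: Optional[PosteriorSample],
        posterior_spec: Optional[ScenarioSpec],
    ):
        self.model = model
        self.table = table
        self.selection = selection
        self.model_choice = choice
        self.posterior = posterior
        self.posterior_spec = posterior_spec

    @property
    def best_scenario(self) -> str:
        return self.model_choice.best

    def scenario_probabilities(self) -> pd.DataFrame:
        return self.model_choice.to_frame()

    def parameter_estimates(self, in_years: bool = False) -> pd.DataFrame:
        """Posterior summaries per parameter; with ``in_years=True`` extra
        rows convert every time parameter (generations) into years using the
        model's life history."""
        if self.posterior is None:
            raise ValueError("no parameter estimation was performed")
        out = self.posterior.summaries.copy()
        if in_years:
            life = self.model.life_history
            extra = []
            for p in out.index:
                if p.startswith("t_"):
                    row = out.loc[p].map(lambda g: generations_to_years(g, life))
                    row.name = f"{p}_years"
                    extra.append(row)
            if extra:
                out = pd.concat([out, pd.DataFrame(extra)])
        return out

    def model_check(
        self, n_pod: int = 1000, seed: int = 0, **kwargs
    ) -> ModelCheckReport:
        """Posterior-predictive check of the estimated scenario."""
        if self.posterior is None or self.posterior_spec is None:
            raise ValueError("no parameter estimation was performed")
        return model_check(
            self.posterior_spec,
            self.posterior,
            self.model.observed,
            self.model.sample_config,
            n_pod,
            seed,
            settings=self.model.settings,
            **kwargs,
        )

    def plot_posterior(self, parameter: str, ax=None, n_grid: int = 256):
        """Weighted posterior density of one parameter (prior range shaded).

        Requires matplotlib.  Returns the axes.
        """
        if self.posterior is None or self.posterior_spec is None:
            raise ValueError("no parameter estimation was performed")
        if parameter not in self.posterior.parameters:
            raise ValueError(
                f"unknown parameter {parameter!r}; have {self.posterior.parameters}"
            )
        import matplotlib.pyplot as plt
        from scipy.stats import gaussian_kde

        if ax is None:
            _, ax = plt.subplots()
        v = self.posterior.adjusted[parameter].to_numpy()
        w = self.posterior.weights
        lo, hi = self.posterior_spec.priors.bounds(parameter)
        grid = np.linspace(lo, hi, n_grid)
        if np.ptp(v) > 0:
            kde = gaussian_kde(v, bw_method="silverman", weights=w / w.sum())
            ax.plot(grid, kde(grid), label="posterior")
        ax.axhline(1.0 / (hi - lo), linestyle="--", color="grey", label="prior")
        s = self.posterior.summaries.loc[parameter]
        ax.axvline(s["mode"], color="k", linewidth=0.8)
        ax.set_xlabel(parameter)
        ax.set_ylabel("density")
        ax.set_title(f"{self.posterior.scenario}: {parameter}")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Human-readable report: observed statistics, scenario probabilities
        with confidence intervals, and posterior parameter summaries (time
        parameters also in years)."""
        lines = []
        lines.append("ABC divergence-scenario analysis")
        lines.append("=" * 60)
        cfg = self.model.sample_config
        sizes = ", ".join(f"{p}={n}" for p, n in cfg.sample_sizes)
        lines.append(f"Samples: {sizes}; locus length {cfg.locus_length} bp")
        counts = {k: int(v) for k, v in self.table.scenario_counts().items()}
        lines.append(f"Reference table: {len(self.table)} simulations ({counts})")
        lines.append(f"Retained for scenario choice: {len(self.selection)} "
                     f"(fraction {self.selection.fraction:g})")
        lines.append("")
        lines.append("Observed summary statistics:")
        for name, v in zip(SUMMARY_STAT_NAMES, self.model.observed):
            lines.append(f"  {name:<14s} {v:.4f}")
        lines.append("")
        lines.append("Scenario probabilities (logistic regression):")
        df = self.scenario_probabilities()
        for s, row in df.iterrows():
            marker = " <- best" if s == self.best_scenario else ""
            lines.append(
                f"  {s:<5s} P = {row['probability']:.4f} "
                f"[{row['ci_low']:.4f}, {row['ci_high']:.4f}] "
                f"(direct {row['direct_frequency']:.4f}){marker}"
            )
        if self.posterior is not None:
            lines.append("")
            lines.append(f"Posterior parameter estimates under {self.posterior.scenario}:")
            est = self.parameter_estimates(in_years=True)
            header = f"  {'parameter':<14s}" + "".join(
                f"{c:>12s}" for c in ("mean", "median", "mode", "q025", "q975")
            )
            lines.append(header)
            for p, row in est.iterrows():
                lines.append(
                    f"  {p:<14s}"
                    + "".join(f"{row[c]:>12.4g}" for c in ("mean", "median", "mode", "q025", "q975"))
                )
        return "\n".join(lines)
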