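"""Sequence evolution along a genealogy under HKY with invariant sites and
gamma rate heterogeneity (HKY+I+Gamma).

A fraction ``p_invariant`` of sites never mutate; the remaining sites carry
relative rates drawn once per dataset from a gamma distribution with shape
``gamma_shape`` (mean one before rescaling).  Rates are rescaled so their mean
over *all* sites is one, making the draw's ``Mu`` the mean per-site, per-
generation substitution rate at stationarity.

Branch evolution is simulated exactly by uniformization of the per-site HKY
continuous-time Markov chain: candidate mutation events arrive as a Poisson
process at a dominating rate and each applies one step of the embedded jump
chain.  Because the per-tree expected substitution count for a short mtDNA
locus is small this is both exact and fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from .coalescent import Genealogy
from .popdata import HaplotypeAlignment

__all__ = ["SubstitutionSettings", "hky_rate_matrix", "draw_site_rates", "evolve_alignment"]


@dataclass(frozen=True)
class SubstitutionSettings:
    """HKY+I+Gamma model settings.

    Parameters
    ----------
    p_invariant : float
        Proportion of invariant sites (each site is independently invariant
        with this probability).
    gamma_shape : float
        Shape of the gamma rate distribution at variable sites.
    kappa : float
        Transition/transversion rate ratio of the HKY model.
    base_freqs : tuple of four floats
        Stationary base frequencies in A, C, G, T order; must sum to one.
    mu : float
        Mean mutation rate per site per generation (the scenario parameter
        ``Mu``); may be overridden per call.
    """

    p_invariant: float = 0.92
    gamma_shape: float = 2.0
    kappa: float = 2.0
    base_freqs: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    mu: float = 1.5e-8

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_invariant <= 1.0):
            raise ValueError(f"p_invariant must be in [0, 1], got {self.p_invariant}")
        if self.gamma_shape <= 0:
            raise ValueError(f"gamma_shape must be positive, got {self.gamma_shape}")
        if self.kappa <= 0:
            raise ValueError(f"kappa must be positive, got {self.kappa}")
        f = np.asarray(self.base_freqs, dtype=float)
        if f.shape != (4,) or (f < 0).any() or abs(f.sum() - 1.0) > 1e-12:
            raise ValueError("base_freqs must be 4 nonnegative values summing to 1")
        if self.mu < 0:
            raise ValueError(f"mu must be nonnegative, got {self.mu}")

    def with_mu(self, mu: float) -> "SubstitutionSettings":
        return SubstitutionSettings(
            self.p_invariant, self.gamma_shape, self.kappa, self.base_freqs, mu
        )

    def with_empirical_freqs(self, aln: HaplotypeAlignment) -> "SubstitutionSettings":
        """Settings with base frequencies taken from an observed alignment."""
        counts = np.array([(aln.matrix == b).sum() for b in range(4)], dtype=float)
        freqs = counts / counts.sum()
        return SubstitutionSettings(
            self.p_invariant, self.gamma_shape, self.kappa, tuple(freqs), self.mu
        )


# transitions: A<->G (0,2), C<->T (1,3)
_TRANSITION = np.zeros((4, 4), dtype=bool)
for _i, _j in ((0, 2), (2, 0), (1, 3), (3, 1)):
    _TRANSITION[_i, _j] = True


def hky_rate_matrix(kappa: float, base_freqs) -> Tuple[np.ndarray, float]:
    """HKY instantaneous rate matrix scaled to one expected substitution per
    unit rate-time at stationarity; returns ``(Q, qmax)`` where ``qmax`` is
    the largest total leaving rate (the uniformization constant)."""
    pi = np.asarray(base_freqs, dtype=float)
    q = np.tile(pi, (4, 1))
    q[_TRANSITION] *= kappa
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    scale = -(pi * np.diag(q)).sum()
    q /= scale
    qmax = float(-np.diag(q).min())
    return q, qmax


def draw_site_rates(
    L: int, settings: SubstitutionSettings, rng: np.random.Generator
) -> np.ndarray:
    """Per-site relative rates: zero at invariant sites, gamma elsewhere,
    rescaled so the mean over all ``L`` sites is one (when any site varies)."""
    if L < 1:
        raise ValueError(f"locus length must be >= 1, got {L}")
    invariant = rng.random(L) < settings.p_invariant
    rates = np.zeros(L)
    n_var = int((~invariant).sum())
    if n_var:
        rates[~invariant] = rng.gamma(settings.gamma_shape, 1.0 / settings.gamma_shape, n_var)
        mean = rates.mean()
        if mean > 0:
            rates /= mean
    return rates


def evolve_alignment(
    g: Genealogy,
    L: int,
    settings: SubstitutionSettings,
    rng: np.random.Generator,
    mu: Optional[float] = None,
    site_rates: Optional[np.ndarray] = None,
) -> HaplotypeAlignment:
    """Evolve an alignment of length ``L`` along genealogy ``g``.

    The root sequence is drawn from the stationary base frequencies; each
    branch then evolves every site by the HKY chain at rate
    ``mu * site_rate``.  Site rates are drawn once and shared by all branches
    (standard +I+Gamma semantics) unless supplied.
    """
    mu = settings.mu if mu is None else mu
    if site_rates is None:
        site_rates = draw_site_rates(L, settings, rng)
    q, qmax = hky_rate_matrix(settings.kappa, settings.base_freqs)
    jump = np.eye(4) + q / qmax  # embedded uniformized jump chain
    jump_cum = np.cumsum(jump, axis=1)

    pi = np.asarray(settings.base_freqs)
    root_seq = rng.choice(4, size=L, p=pi).astype(np.uint8)

    n_nodes = g.n_nodes
    lengths = g.branch_lengths()
    rate_sum = site_rates.sum()
    tbl = lengths.sum()
    lam_total = qmax * mu * tbl * rate_sum

    # place candidate events on (branch, site) with intensity ∝ brlen × rate
    events_by_branch: dict[int, np.ndarray] = {}
    if lam_total > 0:
        n_events = rng.poisson(lam_total)
        if n_events:
            b_idx = rng.choice(n_nodes, size=n_events, p=lengths / tbl)
            s_idx = rng.choice(L, size=n_events, p=site_rates / rate_sum)
            order = np.argsort(b_idx, kind="stable")
            b_sorted, s_sorted = b_idx[order], s_idx[order]
            cuts = np.searchsorted(b_sorted, np.arange(n_nodes + 1))
            for v in range(n_nodes):
                if cuts[v + 1] > cuts[v]:
                    events_by_branch[v] = s_sorted[cuts[v] : cuts[v + 1]]

    sequences = np.zeros((g.n_leaves, L), dtype=np.uint8)
    if g.n_leaves == 1 and n_nodes == 1:
        sequences[0] = root_seq
    else:
        # pre-order traversal carrying each node's sequence
        stack: list[Tuple[int, np.ndarray]] = [(g.root, root_seq)]
        while stack:
            v, seq = stack.pop()
            sites = events_by_branch.get(v)
            if sites is not None:
                # candidate events within a branch are exchangeable in time
                us = rng.random(len(sites))
                for s, u in zip(sites, us):
                    seq[s] = np.searchsorted(jump_cum[seq[s]], u, side="right")
            if v < g.n_leaves:
                sequences[v] = seq
            else:
                stack.append((int(g.left[v]), seq))
                stack.append((int(g.right[v]), seq.copy()))

    ids = []
    counters: dict[str, int] = {}
    for pop in g.leaf_population:
        counters[pop] = counters.get(pop, 0) + 1
        ids.append(f"{pop}_{counters[pop]:04d}")
    return HaplotypeAlignment(ids, list(g.leaf_population), sequences)
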