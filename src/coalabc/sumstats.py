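"""Haplotype summary statistics for labelled alignments.

Implements the 12-statistic ABC summary vector (per-population haplotype
counts, segregating sites and mean pairwise differences, plus the three
pairwise Hudson F_ST values) together with the descriptive diversity
statistics commonly reported for mtDNA surveys: haplotype diversity with its
sampling standard deviation, nucleotide diversity, and AMOVA-style pairwise
Phi_ST with a permutation test.

All computations are column-count based, so they scale linearly in
``n_individuals × L`` rather than quadratically in sample size.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .popdata import HaplotypeAlignment

__all__ = [
    "SUMMARY_STAT_NAMES",
    "n_haplotypes",
    "segregating_sites",
    "mean_pairwise_diff",
    "pairwise_fst",
    "haplotype_diversity",
    "nucleotide_diversity",
    "phi_st_permutation",
    "summary_vector",
    "diversity_report",
]

#: Fixed order of the 12-statistic ABC summary vector for populations (A, B, C)
#: = (SAG, NAG, NC) by default.
SUMMARY_STAT_NAMES = (
    "nhap_SAG",
    "nhap_NAG",
    "nhap_NC",
    "segsites_SAG",
    "segsites_NAG",
    "segsites_NC",
    "mpd_SAG",
    "mpd_NAG",
    "mpd_NC",
    "fst_SAG_NAG",
    "fst_SAG_NC",
    "fst_NAG_NC",
)


def _column_counts(mat: np.ndarray) -> np.ndarray:
    """(4, L) base counts per column."""
    return np.stack([(mat == b).sum(axis=0) for b in range(4)])


def _haplotype_counts(mat: np.ndarray) -> np.ndarray:
    """Multiplicity of each distinct row (hashed by row bytes)."""
    counts: Dict[bytes, int] = {}
    mat = np.ascontiguousarray(mat)
    for i in range(mat.shape[0]):
        key = mat[i].tobytes()
        counts[key] = counts.get(key, 0) + 1
    return np.fromiter(counts.values(), dtype=np.int64)


def _require_pop(aln: HaplotypeAlignment, pop: str, minimum: int = 1) -> np.ndarray:
    mat = aln.submatrix(pop)
    if mat.shape[0] < minimum:
        raise ValueError(
            f"population {pop!r} has {mat.shape[0]} individuals; need >= {minimum}"
        )
    return mat


def n_haplotypes(aln: HaplotypeAlignment, pop: str) -> int:
    """Number of distinct full-length sequences in a population."""
    return int(len(_haplotype_counts(_require_pop(aln, pop))))


def segregating_sites(aln: HaplotypeAlignment, pop: str) -> int:
    """Number of alignment columns with two or more states in a population."""
    counts = _column_counts(_require_pop(aln, pop))
    return int(((counts > 0).sum(axis=0) > 1).sum())


def _mpd_from_matrix(mat: np.ndarray) -> float:
    n = mat.shape[0]
    counts = _column_counts(mat)
    # per column: number of unordered differing pairs = (n^2 - sum c_b^2) / 2
    diff_pairs = (n * n - (counts.astype(np.int64) ** 2).sum(axis=0)) / 2.0
    return float(diff_pairs.sum() / comb(n, 2))


def mean_pairwise_diff(aln: HaplotypeAlignment, pop: str) -> float:
    """Average Hamming distance (in sites) over all unordered pairs."""
    mat = _require_pop(aln, pop, minimum=2)
    return _mpd_from_matrix(mat)


def _between_mpd(mat_a: np.ndarray, mat_b: np.ndarray) -> float:
    na, nb = mat_a.shape[0], mat_b.shape[0]
    ca = _column_counts(mat_a).astype(np.int64)
    cb = _column_counts(mat_b).astype(np.int64)
    same = (ca * cb).sum(axis=0)
    return float((na * nb - same).sum() / (na * nb))


def pairwise_fst(aln: HaplotypeAlignment, pop_a: str, pop_b: str) -> float:
    """Hudson-style F_ST: ``1 - H_w / H_b`` with H_w the unweighted mean of
    the two within-population mean pairwise differences and H_b the mean
    pairwise difference between populations.  Returns 0 when ``H_b == 0``.
    Negative estimates are returned as computed."""
    mat_a = _require_pop(aln, pop_a, minimum=2)
    mat_b = _require_pop(aln, pop_b, minimum=2)
    h_w = 0.5 * (_mpd_from_matrix(mat_a) + _mpd_from_matrix(mat_b))
    h_b = _between_mpd(mat_a, mat_b)
    if h_b == 0.0:
        return 0.0
    return 1.0 - h_w / h_b


def haplotype_diversity(aln: HaplotypeAlignment, pop: str) -> float:
    """Sample-size corrected haplotype diversity ``n (1 - sum p_i^2)/(n-1)``."""
    mat = _require_pop(aln, pop, minimum=2)
    n = mat.shape[0]
    counts = _haplotype_counts(mat)
    p2 = ((counts / n) ** 2).sum()
    return float(n * (1.0 - p2) / (n - 1))


def _haplotype_diversity_sd(counts: np.ndarray) -> float:
    # Nei (1987) sampling variance of heterozygosity applied to haplotypes
    n = counts.sum()
    p = counts / n
    s2 = (p**2).sum()
    s3 = (p**3).sum()
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return float(np.sqrt(max(var, 0.0)))


def nucleotide_diversity(aln: HaplotypeAlignment, pop: str) -> float:
    """Per-site nucleotide diversity: mean pairwise difference / L."""
    return mean_pairwise_diff(aln, pop) / aln.length


def _pi_sd(pi: float, n: int, L: int) -> float:
    # Nei (1987) total variance of nucleotide diversity (sampling + stochastic)
    var = (n + 1.0) / (3.0 * (n - 1.0) * L) * pi + (
        2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    ) * pi**2
    return float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# AMOVA-style Phi_ST
# ---------------------------------------------------------------------------


def _phi_st_from_distances(d: np.ndarray, labels: np.ndarray) -> float:
    """Two-group Phi_ST from a squared-distance matrix (pairwise differences).

    Standard AMOVA variance decomposition: SSD_total is partitioned into
    within- and among-population sums of squares; Phi_ST is the among-group
    share of the total molecular variance.
    """
    n = d.shape[0]
    groups = np.unique(labels)
    ssd_total = d.sum() / (2.0 * n)
    ssd_within = 0.0
    n_sizes = []
    for g in groups:
        idx = labels == g
        ng = int(idx.sum())
        n_sizes.append(ng)
        ssd_within += d[np.ix_(idx, idx)].sum() / (2.0 * ng)
    ssd_among = ssd_total - ssd_within
    df_among = len(groups) - 1
    df_within = n - len(groups)
    if df_within <= 0:
        return 0.0
    msd_within = ssd_within / df_within
    msd_among = ssd_among / df_among
    n_sizes = np.asarray(n_sizes, dtype=float)
    n0 = (n - (n_sizes**2).sum() / n) / df_among
    sigma_a = (msd_among - msd_within) / n0
    denom = sigma_a + msd_within
    if denom == 0.0:
        return 0.0
    return float(sigma_a / denom)


def phi_st_permutation(
    aln: HaplotypeAlignment,
    pop_a: str,
    pop_b: str,
    n_perm: Optional[int] = 999,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float]:
    """Pairwise Phi_ST between two populations with a permutation p-value.

    With ``n_perm`` an integer, individuals are permuted between the two
    groups ``n_perm`` times and ``p = (1 + #{perm >= obs}) / (n_perm + 1)``.
    With ``n_perm=None`` the p-value is exact: every distinct assignment of
    individuals to the two group sizes is enumerated and ``p`` is the
    proportion with a statistic at least as large as observed (the identity
    assignment included).
    """
    mat_a = _require_pop(aln, pop_a, minimum=2)
    mat_b = _require_pop(aln, pop_b, minimum=2)
    mat = np.vstack([mat_a, mat_b])
    na, nb = mat_a.shape[0], mat_b.shape[0]
    n = na + nb
    labels = np.array([0] * na + [1] * nb)
    # pairwise difference matrix (used as AMOVA squared distances)
    d = (mat[:, None, :] != mat[None, :, :]).sum(axis=2).astype(float)
    obs = _phi_st_from_distances(d, labels)
    eps = 1e-12

    if n_perm is None:
        total = 0
        at_least = 0
        for members in combinations(range(n), na):
            lab = np.ones(n, dtype=int)
            lab[list(members)] = 0
            stat = _phi_st_from_distances(d, lab)
            total += 1
            if stat >= obs - eps:
                at_least += 1
        return obs, at_least / total

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1 (or None for exhaustive)")
    if rng is None:
        rng = np.random.default_rng()
    count = 0
    for _ in range(n_perm):
        lab = rng.permutation(labels)
        if _phi_st_from_distances(d, lab) >= obs - eps:
            count += 1
    return obs, (1 + count) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Composite outputs
# ---------------------------------------------------------------------------


def summary_vector(
    aln: HaplotypeAlignment,
    populations: Sequence[str] = ("SAG", "NAG", "NC"),
) -> np.ndarray:
    """The fixed-order 12-statistic ABC summary vector.

    Order: haplotype counts for the three populations, then segregating
    sites, then mean pairwise differences, then pairwise F_ST for
    (1st,2nd), (1st,3rd), (2nd,3rd).
    """
    if len(populations) != 3:
        raise ValueError("summary vector is defined for exactly three populations")
    mats = {p: _require_pop(aln, p, minimum=2) for p in populations}
    out = np.empty(12)
    for i, p in enumerate(populations):
        out[i] = len(_haplotype_counts(mats[p]))
        counts = _column_counts(mats[p])
        out[3 + i] = ((counts > 0).sum(axis=0) > 1).sum()
        out[6 + i] = _mpd_from_matrix(mats[p])
    pairs = [(0, 1), (0, 2), (1, 2)]
    for k, (i, j) in enumerate(pairs):
        a, b = populations[i], populations[j]
        h_w = 0.5 * (out[6 + i] + out[6 + j])
        h_b = _between_mpd(mats[a], mats[b])
        out[9 + k] = 0.0 if h_b == 0.0 else 1.0 - h_w / h_b
    return out


def diversity_report(
    aln: HaplotypeAlignment,
    populations: Optional[Sequence[str]] = None,
    n_perm: int = 999,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-population diversity table and pairwise Phi_ST matrix.

    Returns ``(diversity, phi_st)``: the first with sample size, haplotype
    count, haplotype diversity ± SD and nucleotide diversity ± SD per
    population; the second a long-format table of pairwise Phi_ST values with
    permutation p-values.
    """
    if populations is None:
        populations = aln.population_labels()
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for p in populations:
        mat = _require_pop(aln, p, minimum=2)
        n = mat.shape[0]
        counts = _haplotype_counts(mat)
        h = haplotype_diversity(aln, p)
        pi = nucleotide_diversity(aln, p)
        rows.append(
            {
                "population": p,
                "n": n,
                "n_haplotypes": len(counts),
                "haplotype_diversity": h,
                "haplotype_diversity_sd": _haplotype_diversity_sd(counts),
                "nucleotide_diversity": pi,
                "nucleotide_diversity_sd": _pi_sd(pi, n, aln.length),
            }
        )
    diversity = pd.DataFrame(rows).set_index("population")

    pair_rows = []
    for a, b in combinations(populations, 2):
        phi, p_val = phi_st_permutation(aln, a, b, n_perm=n_perm, rng=rng)
        pair_rows.append({"pop_a": a, "pop_b": b, "phi_st": phi, "p_value": p_val})
    return diversity, pd.DataFrame(pair_rows)
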