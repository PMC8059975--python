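"""Independent oracle implementations used to cross-check the package.

These deliberately use the most transparent method available (exhaustive
enumeration, direct formula evaluation, quadrature) and share no code with
the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import integrate, stats as sps


def brute_trim_length(quals, window: int, min_mean_q: int) -> int:
    """Enumerate every length-``window`` window mean; cut at the first base
    of the first failing window."""
    quals = [int(q) for q in quals]
    n = len(quals)
    if n < window:
        return n
    for s in range(n - window + 1):
        if sum(quals[s : s + window]) / window < min_mean_q:
            return s
    return n


def exhaustive_bipartition(allele_matrix: np.ndarray):
    """Minimum within-group disagreement bipartition of reads.

    ``allele_matrix`` is (n_reads, n_sites) with -1 for uncovered. For each
    bipartition, the cost is the number of (read, site) observations that
    disagree with their group's per-site majority. Returns (cost, frozenset
    of one side's read indices) for a minimal bipartition.
    """
    n = allele_matrix.shape[0]
    best_cost, best_side = None, None
    for bits in itertools.product((0, 1), repeat=n - 1):
        side = np.array((0,) + bits, dtype=bool)
        cost = _group_cost(allele_matrix[side]) + _group_cost(allele_matrix[~side])
        if best_cost is None or cost < best_cost:
            best_cost, best_side = cost, frozenset(np.flatnonzero(side).tolist())
    return best_cost, best_side


def _group_cost(sub: np.ndarray) -> int:
    cost = 0
    for j in range(sub.shape[1]):
        col = sub[:, j]
        col = col[col >= 0]
        if col.size:
            _, counts = np.unique(col, return_counts=True)
            cost += int(col.size - counts.max())
    return cost


def partition_cost(allele_matrix: np.ndarray, side_a) -> int:
    """Disagreement cost of a specific bipartition (same metric as above)."""
    mask = np.zeros(allele_matrix.shape[0], dtype=bool)
    mask[list(side_a)] = True
    return _group_cost(allele_matrix[mask]) + _group_cost(allele_matrix[~mask])


def truncated_lognormal_mean(mu: float, sigma: float, lo: float, hi: float) -> float:
    """Mean of a lognormal restricted to [lo, hi], by quadrature."""
    pdf = sps.lognorm(s=sigma, scale=math.exp(mu)).pdf
    mass, _ = integrate.quad(pdf, lo, hi)
    num, _ = integrate.quad(lambda x: x * pdf(x), lo, hi)
    return num / mass


def poisson_lr_statistic(counts_a, counts_b) -> float:
    """2*(l_full - l_null) for Poisson group means, by direct log-likelihood."""
    def loglik(y, mu):
        y = np.asarray(y, dtype=float)
        return float(np.sum(y * np.log(mu) - mu - [math.lgamma(v + 1) for v in y]))

    y_all = list(counts_a) + list(counts_b)
    mu_all = np.mean(y_all)
    l_null = loglik(y_all, mu_all)
    l_full = loglik(counts_a, np.mean(counts_a)) + loglik(counts_b, np.mean(counts_b))
    return 2.0 * (l_full - l_null)


def ks_distance_enumeration(x, cdf) -> float:
    """sup |ECDF - CDF| via both one-sided envelopes at every sorted point."""
    xs = sorted(x)
    n = len(xs)
    d = 0.0
    for i, v in enumerate(xs, start=1):
        f = cdf(v)
        d = max(d, i / n - f, f - (i - 1) / n)
    return d


def pearson_chisq_uniform(counts) -> float:
    counts = list(counts)
    expected = sum(counts) / len(counts)
    return sum((o - expected) ** 2 / expected for o in counts)


def column_depth(reads) -> dict:
    """Brute-force per-position depth from (offset, length) read placements."""
    depth: dict[int, int] = {}
    for offset, length in reads:
        for p in range(offset, offset + length):
            depth[p] = depth.get(p, 0) + 1
    return depth
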