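"""Two-sample permutation tests with exact and Monte Carlo modes.

Significance of a difference between two groups is assessed by
permuting group labels.  When the pooled sample has fewer than 10
observations every label assignment is enumerated exactly and the
p-value is the fraction of assignments whose statistic is at least as
extreme as the observed one; otherwise the permutation distribution is
sampled (default 1,000,000 draws) and the p-value carries the standard
+1 correction, p = (#extreme + 1)/(n_perm + 1), so it can never be zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np

__all__ = ["PermutationResult", "permutation_test"]

#: Pooled sample size below which all assignments are enumerated.
EXACT_LIMIT = 10

#: Relative tolerance used when comparing permuted statistics to the
#: observed one, so exact ties are not lost to floating-point noise.
_TIE_RTOL = 1e-12

_STATISTICS = {
    "difference_of_means": lambda a, b: a.mean(axis=-1) - b.mean(axis=-1),
    "difference_of_medians": lambda a, b: np.median(a, axis=-1) - np.median(b, axis=-1),
}


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a two-sample permutation test."""

    p_value: float
    observed_statistic: float
    n_permutations_used: int
    method: str  # "exact" | "approximate"
    seed: int | None = None
    statistic: str = "difference_of_means"
    sides: str = "two"


def _extreme(perm_stats: np.ndarray, obs: float, sides: str) -> np.ndarray:
    tol = _TIE_RTOL * max(abs(obs), 1.0)
    if sides == "two":
        return np.abs(perm_stats) >= abs(obs) - tol
    if sides == "greater":
        return perm_stats >= obs - tol
    if sides == "less":
        return perm_stats <= obs + tol
    raise ValueError(f"unknown sides {sides!r}")


def permutation_test(
    a,
    b,
    statistic: str = "difference_of_means",
    sides: str = "two",
    n_perm: int = 1_000_000,
    seed: int | None = None,
    method: str = "auto",
) -> PermutationResult:
    """Two-sample permutation test on the difference of group means.

    With ``method="auto"``, all C(n_a+n_b, n_a) label assignments are
    enumerated exactly when the pooled size is below 10, else the
    permutation distribution is sampled with ``n_perm`` draws and the
    given seed.  ``"exact"`` or ``"approximate"`` forces a mode.
    Deterministic given the seed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("samples must be finite")
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if method not in ("auto", "exact", "approximate"):
        raise ValueError(f"unknown method {method!r}")
    stat = _STATISTICS[statistic]

    obs = float(stat(a, b))
    pooled = np.concatenate([a, b])
    n_a, n = a.size, pooled.size

    use_exact = n < EXACT_LIMIT if method == "auto" else method == "exact"
    if use_exact:
        count = 0
        total = comb(n, n_a)
        idx_all = frozenset(range(n))
        for ia in combinations(range(n), n_a):
            ib = sorted(idx_all - set(ia))
            s = float(stat(pooled[list(ia)], pooled[ib]))
            if _extreme(np.array([s]), obs, sides)[0]:
                count += 1
        return PermutationResult(
            p_value=count / total,
            observed_statistic=obs,
            n_permutations_used=total,
            method="exact",
            seed=seed,
            statistic=statistic,
            sides=sides,
        )

    rng = np.random.default_rng(seed)
    count = 0
    chunk = 100_000
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # m independent permutations of the pooled sample
        order = np.argsort(rng.random((m, n)), axis=1)
        perm = pooled[order]
        stats_m = stat(perm[:, :n_a], perm[:, n_a:])
        count += int(_extreme(stats_m, obs, sides).sum())
        done += m
    return PermutationResult(
        p_value=(count + 1) / (n_perm + 1),
        observed_statistic=obs,
        n_permutations_used=n_perm,
        method="approximate",
        seed=seed,
        statistic=statistic,
        sides=sides,
    )
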