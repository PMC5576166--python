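"""Mann–Whitney U comparison of urban+suburban versus rural indicator values.

Two p-value routes:

* ``asymptotic`` — tie-corrected normal approximation, continuity correction
  on by default (delegates to :func:`scipy.stats.mannwhitneyu`).  This is the
  package default: with very small groups it is conservative relative to the
  exact test, and it is the convention under which province-level workforce
  comparisons are usually reported.
* ``exact`` — full enumeration of the permutation distribution of U over all
  C(n1+n2, n1) assignments of the pooled observations, with midranks, so it
  remains exact under ties.  Refused when the assignment count exceeds
  ``EXACT_MAX_COMBINATIONS``.

``auto`` picks exact for tie-free samples small enough to enumerate,
asymptotic otherwise (mirroring common statistical-software behaviour).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats

from .indicators import SettlementCategory, classify_table, indicator_values
from .region_data import RegionTable, ResourceKind

__all__ = [
    "UTestResult",
    "EXACT_MAX_COMBINATIONS",
    "mann_whitney",
    "compare_settlement_groups",
]

#: Exact enumeration is refused beyond this many label assignments.
EXACT_MAX_COMBINATIONS = 1_000_000


@dataclass(frozen=True)
class UTestResult:
    """Mann–Whitney U statistic for the first group, with a two-sided p."""

    U: float
    n1: int
    n2: int
    method: str  # exact | asymptotic
    p_two_sided: float
    continuity_correction: bool = False
    tie_corrected: bool = False
    resource: ResourceKind | None = None
    basis: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.U <= self.n1 * self.n2):
            raise ValueError(f"U={self.U} outside [0, n1*n2]")
        if not (0 < self.p_two_sided <= 1):
            raise ValueError(f"p={self.p_two_sided} outside (0, 1]")

    @property
    def significance(self) -> str:
        """Star notation: '**' for p<0.01, '*' for p<0.05, '' otherwise."""
        if self.p_two_sided < 0.01:
            return "**"
        if self.p_two_sided < 0.05:
            return "*"
        return ""


def _u_from_midranks(ranks_a: np.ndarray, n1: int, n2: int) -> float:
    """U statistic of group A from its pooled midranks."""
    return float(ranks_a.sum() - n1 * (n1 + 1) / 2)


def _exact_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating assignments of the pooled multiset.

    Under H0 every subset of size n1 of the pooled midranks is equally
    likely.  The two-sided p doubles the smaller tail probability
    (P(U <= u_obs) or P(U >= u_obs)), capped at 1.
    """
    n = len(pooled)
    n2 = n - n1
    ranks = stats.rankdata(pooled)  # midranks handle ties
    lo = hi = 0
    total = 0
    eps = 1e-9
    for idx in itertools.combinations(range(n), n1):
        u = _u_from_midranks(ranks[list(idx)], n1, n2)
        total += 1
        if u <= u_obs + eps:
            lo += 1
        if u >= u_obs - eps:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def mann_whitney(
    a,
    b,
    method: str = "auto",
    continuity_correction: bool = True,
) -> UTestResult:
    """Two-sided Mann–Whitney U test of samples ``a`` versus ``b``.

    Parameters
    ----------
    a, b : array-like
        The two samples; each must be non-empty.
    method : {"auto", "exact", "asymptotic"}
        ``exact`` enumerates the permutation distribution (ties allowed);
        ``asymptotic`` uses the tie-corrected normal approximation;
        ``auto`` chooses exact for small tie-free samples.
    continuity_correction : bool
        Apply the 0.5 continuity correction in the asymptotic method.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    n_comb = comb(n1 + n2, n1)

    if method == "auto":
        method = "exact" if (not has_ties and n_comb <= EXACT_MAX_COMBINATIONS) else "asymptotic"

    ranks = stats.rankdata(pooled)
    u_obs = _u_from_midranks(ranks[:n1], n1, n2)

    if method == "exact":
        if n_comb > EXACT_MAX_COMBINATIONS:
            raise ValueError(
                f"exact enumeration infeasible: C({n1 + n2},{n1})={n_comb} > "
                f"{EXACT_MAX_COMBINATIONS}; use method='asymptotic'"
            )
        p = _exact_p(pooled, n1, u_obs)
        return UTestResult(
            U=u_obs, n1=n1, n2=n2, method="exact", p_two_sided=p,
            continuity_correction=False, tie_corrected=has_ties,
        )
    if method == "asymptotic":
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=continuity_correction,
        )
        return UTestResult(
            U=u_obs, n1=n1, n2=n2, method="asymptotic",
            p_two_sided=float(min(1.0, res.pvalue)),
            continuity_correction=continuity_correction, tie_corrected=has_ties,
        )
    raise ValueError(f"unknown method {method!r}")


def compare_settlement_groups(
    table: RegionTable,
    resource: ResourceKind,
    basis: str,
    method: str = "asymptotic",
    continuity_correction: bool = True,
) -> UTestResult:
    """Urban+suburban versus rural comparison of per-region densities.

    Builds the full-precision indicator values on ``basis``, pools urban and
    suburban regions as group A and rural regions as group B, and runs
    :func:`mann_whitney`.  The default asymptotic+continuity settings
    reproduce conventionally reported province-level p-values.
    """
    cats = classify_table(table)
    values = indicator_values(table, resource, basis)
    is_rural = np.array([cats[name] is SettlementCategory.RURAL for name in table.names])
    a = values[~is_rural]
    b = values[is_rural]
    if a.size == 0:
        raise ValueError("urban+suburban group is empty; comparison undefined")
    if b.size == 0:
        raise ValueError("rural group is empty; comparison undefined")
    res = mann_whitney(a, b, method=method, continuity_correction=continuity_correction)
    return UTestResult(
        U=res.U, n1=res.n1, n2=res.n2, method=res.method,
        p_two_sided=res.p_two_sided,
        continuity_correction=res.continuity_correction,
        tie_corrected=res.tie_corrected,
        resource=ResourceKind(resource), basis=basis,
    )
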