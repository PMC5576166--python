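"""Supply-category cutoffs by deterministic 1-D natural-breaks clustering.

Map classes for choropleth-style reporting are derived by the Fisher–Jenks
optimal-partition criterion: among all contiguous partitions of the sorted
density values into k classes, pick the one minimizing the total
within-class sum of squared deviations.  Solved exactly by dynamic
programming — deterministic, no seed, the standard choice for choropleth
class breaks.

Four classes mirror the conventional red/orange/yellow/green supply palette
(red = inadequate, green = adequate).  On the per-area basis any density of
at most 1 resource per 1 000 km² is forced red regardless of clustering.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from sklearn.base import BaseEstimator

from .indicators import indicator_values
from .region_data import RegionTable, ResourceKind

__all__ = [
    "SupplyCategory",
    "CutoffScheme",
    "NaturalBreaks",
    "INADEQUATE_AREA_DENSITY",
    "natural_breaks",
    "assign_category",
    "categorize_table",
]

#: Area-basis densities at or below this (per 1 000 km²) are always red.
INADEQUATE_AREA_DENSITY = 1.0


class SupplyCategory(str, Enum):
    """Four-level supply adequacy, lowest (red) to highest (green)."""

    RED = "red"
    ORANGE = "orange"
    YELLOW = "yellow"
    GREEN = "green"

    def __str__(self) -> str:  # pragma: no cover
        return self.value


_DEFAULT_LABELS = (
    SupplyCategory.RED,
    SupplyCategory.ORANGE,
    SupplyCategory.YELLOW,
    SupplyCategory.GREEN,
)


@dataclass(frozen=True)
class CutoffScheme:
    """Ordered breakpoints plus the class labels they delimit.

    ``breakpoints`` has length k−1 for k classes and is strictly increasing;
    a value equal to a breakpoint joins the higher class.
    """

    breakpoints: tuple[float, ...]
    labels: tuple[SupplyCategory, ...]
    basis: str | None = None
    resource: ResourceKind | None = None

    def __post_init__(self) -> None:
        bp = tuple(float(b) for b in self.breakpoints)
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "labels", tuple(self.labels))
        if len(self.labels) < 2:
            raise ValueError("a scheme needs at least 2 classes")
        if len(bp) != len(self.labels) - 1:
            raise ValueError("need exactly k-1 breakpoints for k labels")
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")


class NaturalBreaks(BaseEstimator):
    """Fisher–Jenks 1-D clustering into k contiguous classes.

    A scikit-learn-style estimator: ``fit`` on a 1-D array (or (n, 1)
    column) of values, then ``predict`` maps values to class indices
    0..k−1 by the fitted breakpoints (ties to the higher class).

    Parameters
    ----------
    n_classes : int, default 4
        Number of classes k; requires at least k distinct fitted values.

    Attributes
    ----------
    breakpoints_ : ndarray of shape (k−1,)
        Midpoints between the largest value of each class and the smallest
        value of the next, strictly increasing.
    classes_values_ : list of ndarray
        The fitted values, partitioned.
    inertia_ : float
        Total within-class sum of squared deviations of the optimum.
    """

    def __init__(self, n_classes: int = 4):
        self.n_classes = n_classes

    @staticmethod
    def _as_1d(X) -> np.ndarray:
        x = np.asarray(X, dtype=float)
        if x.ndim == 2 and x.shape[1] == 1:
            x = x[:, 0]
        if x.ndim != 1:
            raise ValueError("expected a 1-D array or a single-column 2-D array")
        return x

    def fit(self, X, y=None) -> "NaturalBreaks":
        x = np.sort(self._as_1d(X))
        k = self.n_classes
        if k < 2:
            raise ValueError("n_classes must be at least 2")
        n = len(x)
        if len(np.unique(x)) < k:
            raise ValueError(
                f"need at least {k} distinct values for {k} classes, "
                f"got {len(np.unique(x))}"
            )
        # DP over prefixes: cost[i][j] = min SSD of splitting x[:i] into j classes.
        csum = np.concatenate([[0.0], np.cumsum(x)])
        csum2 = np.concatenate([[0.0], np.cumsum(x * x)])

        def ssd(lo: int, hi: int) -> float:
            # within-class sum of squared deviations of x[lo:hi]
            m = hi - lo
            s = csum[hi] - csum[lo]
            s2 = csum2[hi] - csum2[lo]
            return s2 - s * s / m

        INF = float("inf")
        cost = np.full((n + 1, k + 1), INF)
        back = np.zeros((n + 1, k + 1), dtype=int)
        cost[0, 0] = 0.0
        for j in range(1, k + 1):
            for i in range(j, n + 1):
                best, arg = INF, j - 1
                for s in range(j - 1, i):
                    c = cost[s, j - 1] + ssd(s, i)
                    if c < best - 1e-12:
                        best, arg = c, s
                cost[i, j] = best
                back[i, j] = arg
        bounds = [n]
        i = n
        for j in range(k, 0, -1):
            i = back[i, j]
            bounds.append(i)
        bounds = bounds[::-1]  # 0 = b0 < b1 < ... < bk = n
        self.classes_values_ = [x[bounds[j]:bounds[j + 1]] for j in range(k)]
        self.breakpoints_ = np.array(
            [(x[bounds[j] - 1] + x[bounds[j]]) / 2.0 for j in range(1, k)]
        )
        self.inertia_ = float(cost[n, k])
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "breakpoints_"):
            raise AttributeError("NaturalBreaks instance is not fitted yet")
        x = self._as_1d(X)
        # value equal to a breakpoint joins the higher class
        return np.searchsorted(self.breakpoints_, x, side="right")

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).predict(X)


def natural_breaks(
    values,
    k: int = 4,
    basis: str | None = None,
    resource: ResourceKind | None = None,
) -> CutoffScheme:
    """Optimal k-class cutoff scheme for a set of density values.

    Breakpoints sit at midpoints between adjacent optimal classes.  Labels
    are the red→green supply palette for k=4, or generic ordered labels
    reusing the palette's extremes otherwise (lowest always red, highest
    always green).
    """
    nb = NaturalBreaks(n_classes=k).fit(values)
    if k == 4:
        labels = _DEFAULT_LABELS
    elif k == 2:
        labels = (SupplyCategory.RED, SupplyCategory.GREEN)
    elif k == 3:
        labels = (SupplyCategory.RED, SupplyCategory.YELLOW, SupplyCategory.GREEN)
    else:
        raise ValueError("supply-category labels are defined for k in {2, 3, 4}")
    return CutoffScheme(
        breakpoints=tuple(nb.breakpoints_),
        labels=labels,
        basis=basis,
        resource=ResourceKind(resource) if resource is not None else None,
    )


def assign_category(value: float, scheme: CutoffScheme) -> SupplyCategory:
    """Class of a density value under ``scheme``.

    On the area basis, a value at or below 1 per 1 000 km² is red (the
    inadequate-supply rule) regardless of where the clustering placed its
    breaks; elsewhere values map by breakpoint interval, a value exactly on
    a breakpoint joining the higher class.
    """
    if scheme.basis == "area" and value <= INADEQUATE_AREA_DENSITY:
        return SupplyCategory.RED
    idx = int(np.searchsorted(np.array(scheme.breakpoints), value, side="right"))
    return scheme.labels[idx]


def categorize_table(
    table: RegionTable,
    resource: ResourceKind,
    basis: str,
    k: int = 4,
) -> dict[str, SupplyCategory]:
    """Supply category per region from natural breaks on its indicator values."""
    values = indicator_values(table, resource, basis)
    scheme = natural_breaks(values, k=k, basis=basis, resource=resource)
    return {
        name: assign_category(v, scheme)
        for name, v in zip(table.names, values)
    }
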