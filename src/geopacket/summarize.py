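"""Dataset-level summaries: category distributions and rank correlation.

The category distribution reproduces the kind of breakdown used to show
sampling skew across the urban-rural continuum or climate classes (share
of samples per class, missing values tallied separately).  The rank
correlation is a bespoke Spearman implementation — average ranks for
ties, then the Pearson correlation of the rank vectors — matching the
standard tie-corrected definition; the naive 6·Σd² formula is biased
under ties, which are pervasive in gridded population densities.

Significance uses the large-sample t approximation
``t = rho·sqrt((n-2)/(1-rho²))`` against Student's t with n-2 degrees of
freedom (two-sided); for very small n an exact permutation p-value is
available.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _scipy_stats

from .datapacket import LayerKind
from .errors import (
    DegenerateInput,
    NotCategorical,
    TooFewPairs,
    UnknownCategory,
    UnknownFeature,
)
from .query import AnnotationRecord, CategoricalValue


@dataclass(frozen=True)
class CategorySummary:
    """Distribution of one categorical feature over annotated samples."""

    feature_name: str
    rows: tuple[tuple[int, str, int, float], ...]  # (code, short_label, count, proportion)
    n_annotated: int
    n_missing: int


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    n: int
    p_value: float
    n_dropped: int = 0


def category_distribution(
    annotations: list[AnnotationRecord], feature_name: str
) -> CategorySummary:
    """Count and proportion per category code, sorted by count descending
    (ties by code ascending); missing values excluded from proportions."""
    counts: dict[int, tuple[str, int]] = {}
    n_annotated = 0
    n_missing = 0
    seen_feature = False
    for ann in annotations:
        if feature_name not in ann.values:
            raise UnknownFeature(f"annotations carry no feature {feature_name!r}")
        value = ann.values[feature_name]
        seen_feature = True
        if value is None:
            n_missing += 1
            continue
        if not isinstance(value, CategoricalValue):
            raise NotCategorical(f"feature {feature_name!r} is continuous")
        n_annotated += 1
        short, count = counts.get(value.code, (value.short_label, 0))
        counts[value.code] = (short, count + 1)
    if annotations and not seen_feature:  # pragma: no cover - guarded above
        raise UnknownFeature(feature_name)
    rows = sorted(
        ((code, short, count) for code, (short, count) in counts.items()),
        key=lambda t: (-t[2], t[0]),
    )
    return CategorySummary(
        feature_name=feature_name,
        rows=tuple(
            (code, short, count, count / n_annotated) for code, short, count in rows
        ),
        n_annotated=n_annotated,
        n_missing=n_missing,
    )


def top_share(summary: CategorySummary, codes: set[int]) -> float:
    """Combined proportion of the listed category codes."""
    present = {code for code, _, _, _ in summary.rows}
    unknown = set(codes) - present
    if unknown:
        raise UnknownCategory(f"codes {sorted(unknown)} not in summary {summary.feature_name!r}")
    return sum(prop for code, _, _, prop in summary.rows if code in codes)


# ---------------------------------------------------------------------------
# Spearman rank correlation
# ---------------------------------------------------------------------------

def average_ranks(values: np.ndarray) -> np.ndarray:
    """1-based ranks with ties sharing the average of their positions."""
    values = np.asarray(values, dtype=np.float64)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=np.float64)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman(
    x, y, permutation_p: bool = False
) -> CorrelationResult:
    """Tie-corrected Spearman rank correlation with pairwise deletion.

    Pairs where either value is missing (None or NaN) are dropped and
    counted in ``n_dropped``.  ``permutation_p=True`` computes the exact
    two-sided permutation p-value instead of the t approximation; it is
    restricted to n <= 10.

    Raises
    ------
    TooFewPairs
        Fewer than two complete pairs.
    DegenerateInput
        Either vector has zero rank variance (all values tied).
    """
    xs, ys = [], []
    n_dropped = 0
    for xi, yi in zip(x, y, strict=True):
        if xi is None or yi is None or (isinstance(xi, float) and math.isnan(xi)) or (
            isinstance(yi, float) and math.isnan(yi)
        ):
            n_dropped += 1
            continue
        xs.append(float(xi))
        ys.append(float(yi))
    n = len(xs)
    if n < 2:
        raise TooFewPairs(f"only {n} complete pairs")
    rx = average_ranks(np.array(xs))
    ry = average_ranks(np.array(ys))
    sx = rx - rx.mean()
    sy = ry - ry.mean()
    denom = math.sqrt(float(sx @ sx) * float(sy @ sy))
    if denom == 0.0:
        raise DegenerateInput("zero rank variance: correlation undefined")
    rho = float(sx @ sy) / denom
    rho = max(-1.0, min(1.0, rho))

    if permutation_p:
        if n > 10:
            raise ValueError("exact permutation p-value restricted to n <= 10")
        observed = abs(rho)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            py = ry[list(perm)]
            sp = py - py.mean()
            r = float(sx @ sp) / math.sqrt(float(sx @ sx) * float(sp @ sp))
            if abs(r) >= observed - 1e-12:
                count += 1
            total += 1
        p = count / total
    elif n < 3 or abs(rho) == 1.0:
        p = 0.0 if abs(rho) == 1.0 and n >= 3 else float("nan")
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(_scipy_stats.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, n=n, p_value=p, n_dropped=n_dropped)


def density_diversity_report(pairs) -> CorrelationResult:
    """Rank correlation between population density and a diversity index.

    Thin wrapper over :func:`spearman` fixing the replication-analysis
    conventions: pairwise deletion of incomplete pairs with an explicit
    ``n_dropped``, and at least three complete pairs so the p-value is
    defined.
    """
    pairs = list(pairs)
    xs = [p[0] for p in pairs]
    ys = [p[1] for p in pairs]
    result = spearman(xs, ys)
    if result.n < 3:
        raise TooFewPairs(f"need >= 3 complete pairs, got {result.n}")
    return result
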