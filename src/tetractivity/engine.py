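"""The sequence-activity search engine.

For every candidate feature (degenerate tetranucleotide x weight
profile) the engine rates how robustly the feature correlates with the
measured activity:

1. seven data subsets — the whole dataset plus six half-subsets keyed to
   the lowest / highest / mean-nearest feature and activity values — so
   that a correlation must survive restriction to either tail and to the
   bulk of both variables;
2. in each subset, 11 statistical criteria (five correlation tests, six
   regression-applicability diagnostics), each yielding a significance
   level alpha;
3. every alpha is mapped to a utility v(alpha) in [-1, 1] that is zero
   at alpha = 0.05, positive for significant correlation tests and
   negative for violated applicability assumptions;
4. the score Xi is the mean of the 77 utilities.  Xi > 0 roughly means
   "more than half of the evidence favours a usable correlation".

The best feature is then challenged by a permutation test: activities
are reshuffled and the whole search repeated; the planted feature (or
any feature strongly correlated with it) should not recur.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .alphabet import DegenerateTetra
from .features import FeatureMatrix, FeatureVariant, feature_matrix, variant_grid
from .profiles import WeightProfile
from .sequences import ActivityDataset
from .stats import CRITERIA, all_criteria

ALPHA_REFERENCE = 0.05  # v = 0 here
ALPHA_SATURATION = 1e-6  # v = +1 at and below this significance

_LOG_SAT = math.log10(ALPHA_REFERENCE / ALPHA_SATURATION)
_LOG_ONE = math.log10(1.0 / ALPHA_REFERENCE)


def utility(alpha: float, direction: str = "favourable") -> float:
    """Map a significance level to a utility in [-1, 1].

    Piecewise log-linear: zero at alpha = 0.05, +1 at alpha <= 1e-6,
    -1 at alpha = 1 for the favourable direction (correlation tests,
    where significance is good).  The unfavourable direction (assumption
    checks, where significance means a violated assumption) is negated
    and capped at zero: a significant departure reduces the score down
    to -1, while merely passing an assumption check earns no credit.
    Without the cap every feature would collect ~+0.55 of free utility
    from the six diagnostics and the score of a null feature would sit
    well above zero, which is inconsistent with the score acting as a
    usefulness threshold at zero.
    """
    if not (1e-10 <= alpha <= 1.0):
        raise ValueError(f"alpha out of [1e-10, 1]: {alpha}")
    if alpha <= ALPHA_REFERENCE:
        v = min(1.0, math.log10(ALPHA_REFERENCE / alpha) / _LOG_SAT)
    else:
        v = -min(1.0, math.log10(alpha / ALPHA_REFERENCE) / _LOG_ONE)
    if direction == "favourable":
        return v
    if direction == "unfavourable":
        return min(0.0, -v)
    raise ValueError(f"unknown direction {direction!r}")


@dataclass(frozen=True)
class SubsetSpec:
    subset_id: int  # 1..7
    indices: tuple[int, ...]


def _half_lowest(v: np.ndarray, k: int) -> tuple[int, ...]:
    order = np.argsort(v, kind="stable")
    return tuple(sorted(order[:k]))


def _half_highest(v: np.ndarray, k: int) -> tuple[int, ...]:
    order = np.argsort(-v, kind="stable")
    return tuple(sorted(order[:k]))


def _half_nearest_mean(v: np.ndarray, k: int) -> tuple[int, ...]:
    order = np.argsort(np.abs(v - v.mean()), kind="stable")
    return tuple(sorted(order[:k]))


def make_subsets(ds: ActivityDataset, f: np.ndarray) -> list[SubsetSpec]:
    """The seven analysis subsets for one feature vector.

    (1) all records; then the ceil(n/2) records with (2) lowest / (3)
    highest feature value, (4) nearest the feature mean, (5) lowest /
    (6) highest activity, (7) nearest the activity mean.  Sorting ties
    break by record index.
    """
    n = len(ds)
    if n < 6:
        raise ValueError("need n >= 6 for the seven-subset scheme")
    f = np.asarray(f, dtype=float)
    if f.shape != (n,):
        raise ValueError("feature vector length mismatch")
    x = ds.activity
    k = (n + 1) // 2
    return [
        SubsetSpec(1, tuple(range(n))),
        SubsetSpec(2, _half_lowest(f, k)),
        SubsetSpec(3, _half_highest(f, k)),
        SubsetSpec(4, _half_nearest_mean(f, k)),
        SubsetSpec(5, _half_lowest(x, k)),
        SubsetSpec(6, _half_highest(x, k)),
        SubsetSpec(7, _half_nearest_mean(x, k)),
    ]


@dataclass
class UtilityBreakdown:
    """The full 7 x 11 evidence grid for one feature."""

    alphas: np.ndarray  # (7, 11)
    utilities: np.ndarray  # (7, 11)
    xi: float

    @property
    def criteria(self) -> tuple[str, ...]:
        return CRITERIA


def xi_score(ds: ActivityDataset, f: np.ndarray) -> UtilityBreakdown:
    """Score one feature vector against the dataset activity.

    A constant feature carries no information; by convention its score
    is Xi = -1 (every cell at the worst utility).
    """
    f = np.asarray(f, dtype=float)
    if np.ptp(f) == 0:
        alphas = np.ones((7, 11))
        utilities = -np.ones((7, 11))
        return UtilityBreakdown(alphas=alphas, utilities=utilities, xi=-1.0)
    subsets = make_subsets(ds, f)
    alphas = np.empty((7, 11))
    utilities = np.empty((7, 11))
    x = ds.activity
    for row, sub in enumerate(subsets):
        idx = list(sub.indices)
        results = all_criteria(x[idx], f[idx])
        for col, res in enumerate(results):
            alphas[row, col] = res.alpha
            utilities[row, col] = utility(res.alpha, res.direction)
    return UtilityBreakdown(alphas=alphas, utilities=utilities, xi=float(utilities.mean()))


@dataclass
class RankedVariant:
    variant: FeatureVariant
    xi: float
    pearson_r: float  # on the full dataset
    feature: np.ndarray


@dataclass
class SearchResult:
    ranked: list[RankedVariant]
    best: RankedVariant | None  # None <=> no useful correlation (max Xi <= 0)
    screen_kept: int
    n_variants: int

    @property
    def useful(self) -> bool:
        return self.best is not None


class _ColumnStats:
    """Cached per-column moments of a feature matrix, reused across the
    permutation cycles (the features never change, only the activity)."""

    def __init__(self, values: np.ndarray):
        n = values.shape[0]
        self.col_sum = values.sum(axis=0)
        # clip tiny negatives from cancellation on (near-)constant columns
        self.col_ss = np.maximum(
            np.einsum("ij,ij->j", values, values) - self.col_sum**2 / n, 0.0
        )


def _pearson_screen(
    values: np.ndarray, x: np.ndarray, stats: _ColumnStats | None = None
) -> np.ndarray:
    """Pearson r of every feature column against x; constant columns
    score 0.  Avoids materializing centred copies of the matrix."""
    if stats is None:
        stats = _ColumnStats(values)
    xc = x - x.mean()
    num = xc @ values  # centred x makes column centring unnecessary
    den = np.sqrt(stats.col_ss * (xc @ xc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / den, 0.0)
    return r


def _top_k_by_abs(r: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest |r|, ordered by (|r| desc, index asc)."""
    a = np.abs(r)
    if k < a.size:
        cand = np.argpartition(-a, k - 1)[:k]
    else:
        cand = np.arange(a.size)
    return cand[np.lexsort((cand, -a[cand]))]


def _tie_key(rv: RankedVariant, variant_index: dict[FeatureVariant, int]):
    # more specific pattern first, then lexicographic, then profile index
    return (
        -rv.xi,
        rv.variant.tetra.expansion_size,
        rv.variant.tetra.codes,
        variant_index[rv.variant],
    )


def search(
    ds: ActivityDataset,
    variants: list[FeatureVariant] | None = None,
    *,
    profiles: list[WeightProfile] | None = None,
    tetra_space: list[DegenerateTetra] | None = None,
    screen_top_k: int = 1000,
    min_xi: float = 0.0,
    precomputed: FeatureMatrix | None = None,
    activity: np.ndarray | None = None,
    column_stats: "_ColumnStats | None" = None,
) -> SearchResult:
    """Two-stage search over the variant space.

    Stage 1 screens every variant by |Pearson r| on the full dataset;
    stage 2 computes the full 77-test Xi for the ``screen_top_k``
    screened leaders.  The winner is the highest-Xi variant provided
    Xi > ``min_xi``; otherwise the result records that no useful
    correlation exists.  Ties break toward the more specific pattern
    (fewest concrete expansions), then lexicographically.

    The variant space is given either directly (``variants``), as a
    ``tetra_space x profiles`` grid, or as a ``precomputed`` feature
    matrix (used by the permutation test to avoid recomputation).
    ``activity`` overrides the dataset activity vector.
    """
    if precomputed is None:
        if variants is None:
            if profiles is None or tetra_space is None:
                raise ValueError("provide variants, a (profiles, tetra_space) grid, "
                                 "or a precomputed feature matrix")
            variants = variant_grid(tetra_space, profiles)
        if not variants:
            raise ValueError("empty variant space")
        precomputed = feature_matrix(ds, variants)
    fm = precomputed
    if not fm.variants:
        raise ValueError("empty variant space")
    if screen_top_k < 1:
        raise ValueError("screen_top_k must be >= 1")
    x = ds.activity if activity is None else np.asarray(activity, dtype=float)
    r = _pearson_screen(fm.values, x, column_stats)
    k = min(screen_top_k, len(fm.variants))
    order = _top_k_by_abs(r, k)
    scored_ds = ds if activity is None else ds.with_activity(x)
    ranked = [
        RankedVariant(
            variant=fm.variants[j],
            xi=xi_score(scored_ds, fm.values[:, j]).xi,
            pearson_r=float(r[j]),
            feature=fm.values[:, j],
        )
        for j in order
    ]
    variant_index = {v: i for i, v in enumerate(fm.variants)}
    ranked.sort(key=lambda rv: _tie_key(rv, variant_index))
    best = ranked[0] if ranked and ranked[0].xi > min_xi else None
    return SearchResult(ranked=ranked, best=best, screen_kept=k, n_variants=len(fm.variants))


@dataclass
class PermutationOutcome:
    recurrences: int
    cycles: int
    alpha: float
    significant: bool  # True <=> the original finding survives


def permutation_verify(
    ds: ActivityDataset,
    best: RankedVariant,
    fm: FeatureMatrix,
    *,
    cycles: int = 100,
    corr_threshold: float = 0.8,
    screen_top_k: int = 1000,
    seed: int = 0,
) -> PermutationOutcome:
    """Permutation challenge of a search winner.

    Each cycle reshuffles the activities against the sequences (seeded)
    and re-runs the identical search over the same variant space.  A
    cycle scores a *recurrence* when its winner is the original variant,
    or any variant whose feature vector on the original dataset has
    |Pearson r| >= ``corr_threshold`` with the original winner's.

    Under the null that winners arise by chance at rate 0.05 per cycle,
    the lower binomial tail P(X <= recurrences) is the reported alpha;
    zero recurrences in 100 cycles gives 0.95**100 ~ 0.0059, i.e. the
    absence of recurrence is itself significant evidence.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    rng = np.random.default_rng(seed)
    fbest = best.feature
    recurrences = 0
    n = len(ds)
    stats = _ColumnStats(fm.values)
    for _ in range(cycles):
        perm = rng.permutation(n)
        res = search(
            ds, precomputed=fm, screen_top_k=screen_top_k,
            activity=ds.activity[perm], column_stats=stats,
        )
        if res.best is None:
            continue
        if res.best.variant == best.variant:
            recurrences += 1
            continue
        r = np.corrcoef(fbest, res.best.feature)[0, 1]
        if np.isfinite(r) and abs(r) >= corr_threshold:
            recurrences += 1
    alpha = float(sps.binom.cdf(recurrences, cycles, ALPHA_REFERENCE))
    return PermutationOutcome(
        recurrences=recurrences, cycles=cycles, alpha=alpha,
        significant=alpha < ALPHA_REFERENCE,
    )
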