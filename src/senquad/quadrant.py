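"""Median-quadrant assignment and one-sided Fisher exact enrichment.

Samples are placed in the 2D plane of two gene-set scores and partitioned
into quadrants by the score medians (Q1 upper-right, Q2 upper-left, Q3
lower-left, Q4 lower-right; a value equal to a split falls on the low side).
Enrichment of a sample group in a quadrant is tested with the one-sided
Fisher exact test for the 2×2 table (group × in/out of quadrant), reporting

* the exact hypergeometric tail p-value,
* the conditional maximum-likelihood odds ratio — the value of the odds
  ratio ψ maximizing the Fisher noncentral hypergeometric likelihood of the
  observed cell given all table margins, and
* the exact one-sided confidence bound — the ψ at which the observed tail
  has probability exactly α.

These are the conventions of R's ``fisher.test`` (one-sided interval printed
as "L–Inf"), which this module reproduces natively from the likelihood. The
conditional MLE is 0 or +inf when the observed cell sits at the boundary of
the hypergeometric support.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import gammaln, logsumexp
from scipy.stats import hypergeom

__all__ = [
    "QuadrantAssignment",
    "ContingencyTable2x2",
    "EnrichmentResult",
    "assign_quadrants",
    "contingency",
    "fisher_exact_one_sided",
    "enrichment_scan",
    "scatter_export",
    "or_bar_export",
]

QUADRANTS = ("Q1", "Q2", "Q3", "Q4")
Alternative = Literal["greater", "less", "two-sided"]


class EnrichmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Quadrant assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuadrantAssignment:
    """Per-sample quadrant labels plus the splits that produced them.

    ``table`` has columns x, y, quadrant indexed by sample id. The tie rule
    is ≤ split → low side, so "all identical" inputs land in Q3.
    """

    table: pd.DataFrame
    x_split: float
    y_split: float
    split_method: str

    @property
    def counts(self) -> dict[str, int]:
        c = self.table["quadrant"].value_counts()
        return {q: int(c.get(q, 0)) for q in QUADRANTS}

    @property
    def n(self) -> int:
        return len(self.table)


def assign_quadrants(
    x: pd.Series | Sequence[float],
    y: pd.Series | Sequence[float],
    split_method: str = "median",
    x_split: float | None = None,
    y_split: float | None = None,
) -> QuadrantAssignment:
    """Partition samples into quadrants by the two score medians.

    Samples with a missing score on either axis are excluded with a warning
    (listwise deletion); fewer than 4 remaining samples is an error. With
    ``split_method="fixed"`` both splits must be supplied.
    """
    xs = pd.Series(x, dtype=float)
    ys = pd.Series(y, dtype=float)
    if not isinstance(x, pd.Series):
        xs.index = ys.index if isinstance(y, pd.Series) else range(len(xs))
    if not isinstance(y, pd.Series):
        ys.index = xs.index
    if len(xs) != len(ys) or not xs.index.equals(ys.index):
        raise EnrichmentError("x and y scores must be aligned (same samples)")

    keep = xs.notna() & ys.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"excluding {n_dropped} sample(s) with absent scores from the "
            "quadrant analysis",
            stacklevel=2,
        )
        xs, ys = xs[keep], ys[keep]
    if len(xs) < 4:
        raise EnrichmentError(f"need ≥4 scored samples, got {len(xs)}")

    if split_method == "median":
        xsplit = float(np.median(xs.to_numpy()))
        ysplit = float(np.median(ys.to_numpy()))
    elif split_method == "fixed":
        if x_split is None or y_split is None:
            raise EnrichmentError("split_method='fixed' requires x_split and y_split")
        xsplit, ysplit = float(x_split), float(y_split)
    else:
        raise EnrichmentError(f"unknown split_method {split_method!r}")

    hi_x = xs > xsplit
    hi_y = ys > ysplit
    quadrant = np.where(
        hi_x & hi_y, "Q1", np.where(~hi_x & hi_y, "Q2", np.where(~hi_x, "Q3", "Q4"))
    )
    table = pd.DataFrame({"x": xs, "y": ys, "quadrant": quadrant})
    return QuadrantAssignment(table, xsplit, ysplit, split_method)


# ---------------------------------------------------------------------------
# 2×2 contingency
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for (target group vs others) × (target quadrant vs elsewhere).

    a = target-group samples in the target quadrant, b = target-group
    elsewhere, c = other samples in the quadrant, d = other samples
    elsewhere.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if not isinstance(cell, (int, np.integer)) or cell < 0:
                raise EnrichmentError(
                    f"table cells must be nonnegative integers, got {cell!r}"
                )

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


def contingency(
    assignment: QuadrantAssignment,
    groups: pd.Series | Sequence[str],
    target_quadrant: str,
    target_group: str,
    other_group: str | None = None,
) -> ContingencyTable2x2:
    """Cross-tabulate quadrant membership against a two-group label.

    With ``other_group=None`` every non-target sample forms the background;
    otherwise samples outside {target_group, other_group} are excluded with
    a warning.
    """
    if target_quadrant not in QUADRANTS:
        raise EnrichmentError(f"unknown quadrant {target_quadrant!r}")
    g = pd.Series(groups)
    if not isinstance(groups, pd.Series):
        g.index = assignment.table.index
    g = g.reindex(assignment.table.index)
    if g.isna().any():
        warnings.warn(
            f"excluding {int(g.isna().sum())} sample(s) without a group label",
            stacklevel=2,
        )
    if target_group not in set(g.dropna()):
        raise EnrichmentError(
            f"target group {target_group!r} absent from labels "
            f"{sorted(set(map(str, g.dropna())))}"
        )
    if other_group is not None:
        keep = g.isin([target_group, other_group])
        n_excluded = int((~keep & g.notna()).sum())
        if n_excluded:
            warnings.warn(
                f"excluding {n_excluded} sample(s) outside groups "
                f"{{{target_group!r}, {other_group!r}}}",
                stacklevel=2,
            )
        g = g[keep]
    else:
        g = g.dropna()

    in_quad = assignment.table.loc[g.index, "quadrant"] == target_quadrant
    is_target = g == target_group
    a = int((is_target & in_quad).sum())
    b = int((is_target & ~in_quad).sum())
    c = int((~is_target & in_quad).sum())
    d = int((~is_target & ~in_quad).sum())
    return ContingencyTable2x2(a, b, c, d)


# ---------------------------------------------------------------------------
# Fisher exact test with conditional-MLE odds ratio
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EnrichmentResult:
    table: ContingencyTable2x2
    p: float
    or_cmle: float
    ci_lower: float
    ci_upper: float
    alpha: float
    alternative: str
    target_quadrant: str | None = None
    target_group: str | None = None
    comparison: str | None = None


def _support(table: ContingencyTable2x2) -> tuple[int, int, int, int, int]:
    """(n, row1, col1, x_min, x_max) for the conditional distribution of a."""
    n = table.n
    row1 = table.a + table.b
    col1 = table.a + table.c
    x_min = max(0, row1 + col1 - n)
    x_max = min(row1, col1)
    return n, row1, col1, x_min, x_max


def _log_weights(n: int, row1: int, col1: int, x: np.ndarray) -> np.ndarray:
    """log C(row1, x) + log C(n−row1, col1−x) over the support."""
    return (
        gammaln(row1 + 1)
        - gammaln(x + 1)
        - gammaln(row1 - x + 1)
        + gammaln(n - row1 + 1)
        - gammaln(col1 - x + 1)
        - gammaln(n - row1 - (col1 - x) + 1)
    )


def _conditional_pmf_log(
    log_w: np.ndarray, x: np.ndarray, log_psi: float
) -> np.ndarray:
    """Log pmf of the Fisher noncentral hypergeometric at odds ratio e^log_psi."""
    logits = log_w + x * log_psi
    return logits - logsumexp(logits)


def _cmle_or(table: ContingencyTable2x2) -> float:
    """Odds ratio maximizing the noncentral hypergeometric likelihood.

    Solves the score equation E_ψ[X] = a on the log scale; boundary cells
    give 0 / +inf.
    """
    n, row1, col1, x_min, x_max = _support(table)
    a = table.a
    if x_min == x_max:
        return math.nan  # degenerate support: OR not identifiable
    if a == x_min:
        return 0.0
    if a == x_max:
        return math.inf
    x = np.arange(x_min, x_max + 1)
    log_w = _log_weights(n, row1, col1, x)

    def score(log_psi: float) -> float:
        p = np.exp(_conditional_pmf_log(log_w, x, log_psi))
        return float(p @ x) - a

    lo, hi = -1.0, 1.0
    while score(lo) > 0:
        lo *= 2
        if lo < -500:  # pragma: no cover - guarded by boundary checks above
            return 0.0
    while score(hi) < 0:
        hi *= 2
        if hi > 500:  # pragma: no cover
            return math.inf
    return float(math.exp(brentq(score, lo, hi, xtol=1e-12, rtol=1e-14)))


def _tail_prob(
    table: ContingencyTable2x2, log_psi: float, tail: Literal["ge", "le"]
) -> float:
    """P_ψ(X ≥ a) or P_ψ(X ≤ a) under the noncentral hypergeometric."""
    n, row1, col1, x_min, x_max = _support(table)
    x = np.arange(x_min, x_max + 1)
    log_p = _conditional_pmf_log(_log_weights(n, row1, col1, x), x, log_psi)
    mask = x >= table.a if tail == "ge" else x <= table.a
    return float(np.exp(logsumexp(log_p[mask])))


def _exact_bound(
    table: ContingencyTable2x2, alpha: float, tail: Literal["ge", "le"]
) -> float:
    """Solve P_ψ(tail at a) = alpha for ψ.

    ``tail="ge"`` gives the one-sided lower bound for alternative="greater"
    (P_ψ(X ≥ a) increases with ψ); ``tail="le"`` the upper bound for "less".
    """
    _, _, _, x_min, x_max = _support(table)
    if tail == "ge" and table.a == x_min:
        return 0.0
    if tail == "le" and table.a == x_max:
        return math.inf

    def f(log_psi: float) -> float:
        return _tail_prob(table, log_psi, tail) - alpha

    # f increases in ψ for "ge", decreases for "le"
    lo, hi = -1.0, 1.0
    while f(lo) > 0 if tail == "ge" else f(lo) < 0:
        lo *= 2
        if lo < -700:
            return 0.0
    while f(hi) < 0 if tail == "ge" else f(hi) > 0:
        hi *= 2
        if hi > 700:
            return math.inf
    return float(math.exp(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)))


def _p_one_sided(table: ContingencyTable2x2, alternative: Alternative) -> float:
    """Exact hypergeometric p-value at the null ψ = 1."""
    n, row1, col1, _, _ = _support(table)
    if alternative == "greater":
        return float(hypergeom.sf(table.a - 1, n, col1, row1))
    if alternative == "less":
        return float(hypergeom.cdf(table.a, n, col1, row1))
    # two-sided, point-probability method: sum all outcomes no more likely
    # than the observed one (with a small relative tolerance, as R does)
    _, _, _, x_min, x_max = _support(table)
    x = np.arange(x_min, x_max + 1)
    pmf = hypergeom.pmf(x, n, col1, row1)
    p_obs = hypergeom.pmf(table.a, n, col1, row1)
    return float(min(1.0, pmf[pmf <= p_obs * (1 + 1e-7)].sum()))


def fisher_exact_one_sided(
    table: ContingencyTable2x2 | tuple[int, int, int, int],
    alternative: Alternative = "greater",
    alpha: float = 0.05,
    target_quadrant: str | None = None,
    target_group: str | None = None,
    comparison: str | None = None,
) -> EnrichmentResult:
    """Fisher exact test with conditional-MLE OR and exact one-sided CI.

    The null hypothesis is odds ratio = 1. For ``alternative="greater"`` the
    p-value is the upper hypergeometric tail P(X ≥ a) and the interval is
    [ci_lower, +inf) with ci_lower solving P_ψ(X ≥ a) = α; symmetrically for
    "less". The two-sided variant uses the point-probability method with an
    α/2 bound on each side. An empty margin makes the odds ratio
    unidentifiable: p = 1, OR and CI are reported as NaN with a warning.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    if not 0 < alpha < 1:
        raise EnrichmentError(f"alpha must be in (0,1), got {alpha}")
    if alternative not in ("greater", "less", "two-sided"):
        raise EnrichmentError(f"unknown alternative {alternative!r}")

    n, row1, col1, x_min, x_max = _support(table)
    if row1 == 0 or col1 == 0 or row1 == n or col1 == n:
        warnings.warn(
            f"table {table.as_tuple()} has an empty margin; odds ratio "
            "undefined",
            stacklevel=2,
        )
        return EnrichmentResult(
            table, 1.0, math.nan, math.nan, math.nan, alpha, alternative,
            target_quadrant, target_group, comparison,
        )

    p = _p_one_sided(table, alternative)
    or_cmle = _cmle_or(table)
    if alternative == "greater":
        ci_lower = _exact_bound(table, alpha, "ge")
        ci_upper = math.inf
    elif alternative == "less":
        ci_lower = 0.0
        ci_upper = _exact_bound(table, alpha, "le")
    else:
        ci_lower = _exact_bound(table, alpha / 2, "ge")
        ci_upper = _exact_bound(table, alpha / 2, "le")
    return EnrichmentResult(
        table, p, or_cmle, ci_lower, ci_upper, alpha, alternative,
        target_quadrant, target_group, comparison,
    )


# ---------------------------------------------------------------------------
# Scan over quadrants / groups
# ---------------------------------------------------------------------------


def enrichment_scan(
    score_tbl: pd.DataFrame,
    x_set: str,
    y_set: str,
    group_col: str,
    target_group: str,
    quadrants: Sequence[str] = QUADRANTS,
    alternative: Alternative = "greater",
    alpha: float = 0.05,
    split_method: str = "median",
    other_group: str | None = None,
    include_complement: bool = True,
) -> tuple[QuadrantAssignment, list[EnrichmentResult]]:
    """Quadrant enrichment of a target group over two score columns.

    Assigns quadrants from the ``x_set``/``y_set`` score columns, then tests
    the target group in each requested quadrant. When the comparison has
    exactly two groups and ``include_complement`` is set, the complementary
    group's results are appended (for paired OR bar plots).
    """
    for col in (x_set, y_set, group_col):
        if col not in score_tbl.columns:
            raise EnrichmentError(
                f"column {col!r} not in score table (have {list(score_tbl.columns)})"
            )
    for q in quadrants:
        if q not in QUADRANTS:
            raise EnrichmentError(f"unknown quadrant {q!r}")

    assignment = assign_quadrants(
        score_tbl[x_set], score_tbl[y_set], split_method=split_method
    )
    groups = score_tbl[group_col].reindex(assignment.table.index)
    comparison = f"{x_set}~{y_set}"

    target_groups = [target_group]
    if include_complement:
        present = set(map(str, groups.dropna()))
        if other_group is not None:
            others = [other_group]
        else:
            others = sorted(present - {target_group})
        if len(others) == 1:
            target_groups.append(others[0])

    results: list[EnrichmentResult] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # per-table margin warnings, if any
        for tg in target_groups:
            for q in quadrants:
                tbl = contingency(assignment, groups, q, tg, other_group=other_group
                                  if tg == target_group else None)
                results.append(
                    fisher_exact_one_sided(
                        tbl, alternative=alternative, alpha=alpha,
                        target_quadrant=q, target_group=tg, comparison=comparison,
                    )
                )
    return assignment, results


# ---------------------------------------------------------------------------
# Plot-data exports
# ---------------------------------------------------------------------------


def scatter_export(
    assignment: QuadrantAssignment, groups: pd.Series | Sequence[str]
) -> pd.DataFrame:
    """Tidy per-sample table (sample, x, y, quadrant, group) for scatter plots."""
    g = pd.Series(groups)
    if not isinstance(groups, pd.Series):
        g.index = assignment.table.index
    out = assignment.table.copy()
    out.insert(0, "sample", out.index)
    out["group"] = g.reindex(out.index)
    return out.reset_index(drop=True)


def or_bar_export(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """One row per test (comparison, quadrant, group, counts, OR, CI, p)."""
    cols = [
        "comparison", "quadrant", "group", "a", "b", "c", "d",
        "odds_ratio", "ci_lower", "ci_upper", "p", "alpha", "alternative",
    ]
    rows = [
        {
            "comparison": r.comparison,
            "quadrant": r.target_quadrant,
            "group": r.target_group,
            "a": r.table.a,
            "b": r.table.b,
            "c": r.table.c,
            "d": r.table.d,
            "odds_ratio": r.or_cmle,
            "ci_lower": r.ci_lower,
            "ci_upper": r.ci_upper,
            "p": r.p,
            "alpha": r.alpha,
            "alternative": r.alternative,
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=cols)
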