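"""Cohort-level inference: contingency tests, rank tests, odds ratios, ROC.

The analysis cascade this module supports:

* χ²/Fisher tests on response-rate contingency tables (test choice follows
  the conventional rule: Yates-corrected χ² for 2×2 tables, Fisher's exact
  test when any expected count drops below 5, plain Pearson for r×c);
* Mann-Whitney U comparisons of continuous microenvironment metrics between
  response groups, exact for small samples, asymptotic (tie-corrected, no
  continuity correction) otherwise;
* median (Q1, Q3) group summaries;
* median-split dichotomization feeding univariate odds ratios with Wald
  confidence intervals (Haldane–Anscombe correction on zero cells);
* empirical ROC curves with trapezoidal AUC (cross-checked against the
  concordance U-statistic identity) and the Youden-optimal operating point.

All tests are two-sided at α = 0.05; no multiple-testing correction is
applied, but report builders count the tests they run.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, ValidationError

__all__ = [
    "ContingencyTable", "TestResult", "OrResult", "RocResult",
    "build_contingency", "chi2_test", "fisher_exact_2x2",
    "categorical_test", "mann_whitney", "median_iqr", "dichotomize",
    "univariate_or", "roc_curve",
]


@dataclass
class ContingencyTable:
    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2:
            raise ValidationError("contingency counts must be 2-D")
        if (self.counts < 0).any():
            raise ValidationError("contingency counts must be non-negative")
        r, c = self.counts.shape
        if len(self.row_labels) != r or len(self.col_labels) != c:
            raise ValidationError("label lengths do not match counts shape")

    @property
    def shape(self):
        return self.counts.shape

    def expected(self) -> np.ndarray:
        n = self.counts.sum()
        return np.outer(self.counts.sum(1), self.counts.sum(0)) / n

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels,
                            columns=self.col_labels)


@dataclass
class TestResult:
    method: str  # pearson_chi2 | yates_chi2 | fisher_exact | mw_exact | mw_asymptotic
    statistic: float
    p: float
    df: int | None = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class OrResult:
    odds_ratio: float
    ci_lower: float
    ci_upper: float
    p: float
    split_rule: str
    corrected: bool = False  # Haldane–Anscombe +0.5 applied
    table: np.ndarray | None = None


@dataclass
class RocResult:
    # operating points as (threshold, sensitivity, specificity), thresholds
    # descending so sensitivity is non-decreasing along the list
    points: list[tuple[float, float, float]]
    auc: float
    youden_threshold: float
    sensitivity: float
    specificity: float
    flipped: bool  # scores were negated so that AUC >= 0.5


def build_contingency(
    patients: pd.DataFrame,
    row_var: str,
    col_var: str,
    filter: Mapping[str, object] | None = None,
    *,
    row_order: Sequence[str] | None = None,
    col_order: Sequence[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate two categorical patient variables.

    ``filter`` restricts to patients matching every key=value pair (e.g.
    ``{"regimen": "NAIC"}``). Labels keep first-appearance order of the
    input unless an explicit order is given.
    """
    df = patients
    if filter:
        mask = pd.Series(True, index=df.index)
        for k, v in filter.items():
            if k not in df.columns:
                raise ConfigError(f"filter variable {k!r} not in table")
            mask &= df[k] == v
        df = df[mask]
        if df.empty:
            raise ConfigError(f"filter {dict(filter)!r} matches no patients")
    for v in (row_var, col_var):
        if v not in df.columns:
            raise ConfigError(f"variable {v!r} not in table")
    rows = list(dict.fromkeys(df[row_var])) if row_order is None else list(row_order)
    cols = list(dict.fromkeys(df[col_var])) if col_order is None else list(col_order)
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    for i, rv in enumerate(rows):
        for j, cv in enumerate(cols):
            counts[i, j] = int(((df[row_var] == rv) & (df[col_var] == cv)).sum())
    return ContingencyTable(counts, [str(r) for r in rows], [str(c) for c in cols])


def _as_counts(table) -> np.ndarray:
    if isinstance(table, ContingencyTable):
        return table.counts
    return np.asarray(table, dtype=np.int64)


def chi2_test(table, correction: str = "auto") -> TestResult:
    """Pearson χ² with df=(r−1)(c−1); Yates continuity correction on 2×2.

    ``correction``: ``"auto"`` applies Yates iff the table is 2×2; ``"on"``
    forces it (2×2 only); ``"off"`` gives plain Pearson.
    """
    counts = _as_counts(table)
    r, c = counts.shape
    if r < 2 or c < 2:
        raise ValidationError("chi2 test needs at least a 2x2 table")
    if counts.sum(0).min() == 0 or counts.sum(1).min() == 0:
        raise ValidationError("chi2 test undefined: a marginal total is zero")
    if correction not in ("auto", "on", "off"):
        raise ConfigError(f"unknown correction mode {correction!r}")
    use_yates = (correction == "on") or (correction == "auto" and (r, c) == (2, 2))
    if use_yates and (r, c) != (2, 2):
        raise ConfigError("Yates correction applies to 2x2 tables only")
    stat, p, df, _ = sps.chi2_contingency(counts, correction=use_yates)
    return TestResult("yates_chi2" if use_yates else "pearson_chi2",
                      float(stat), float(p), df=int(df))


def fisher_exact_2x2(table) -> TestResult:
    """Fisher's exact test, two-sided by the point-probability rule.

    p is the sum of hypergeometric probabilities, over all tables with the
    observed margins, whose point probability does not exceed the observed
    table's.
    """
    counts = _as_counts(table)
    if counts.shape != (2, 2):
        raise ValidationError("Fisher exact test requires a 2x2 table")
    if counts.sum(0).min() == 0 or counts.sum(1).min() == 0:
        raise ValidationError("Fisher test undefined: a marginal total is zero")
    odds, p = sps.fisher_exact(counts, alternative="two-sided")
    return TestResult("fisher_exact", float(odds), float(p))


def categorical_test(table, *, min_expected: float = 5.0) -> TestResult:
    """Dispatch: 2×2 → Yates χ², or Fisher when any expected count < 5;
    larger tables → Pearson χ²."""
    counts = _as_counts(table)
    ct = table if isinstance(table, ContingencyTable) else ContingencyTable(
        counts, [str(i) for i in range(counts.shape[0])],
        [str(j) for j in range(counts.shape[1])])
    if counts.shape == (2, 2) and ct.expected().min() < min_expected:
        return fisher_exact_2x2(counts)
    return chi2_test(counts, correction="auto")


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _u_from_midranks(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(U for x, tie-corrected variance of U) from pooled midranks."""
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t ** 3 - t).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    return float(u1), float(var)


def _exact_u_sf_counts(n1: int, n2: int) -> np.ndarray:
    """counts[u] = number of arrangements with U statistic u (no ties).

    Classical recursion on the generating function of the Mann-Whitney
    U distribution: f(n1, n2, u) = f(n1-1, n2, u-n2) + f(n1, n2-1, u).
    """
    max_u = n1 * n2
    # dp over a table of partial counts
    table = np.zeros((n1 + 1, n2 + 1, max_u + 1), dtype=float)
    table[0, :, 0] = 1.0
    table[:, 0, 0] = 1.0
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            for u in range(0, i * j + 1):
                a = table[i - 1, j, u - j] if u >= j else 0.0
                b = table[i, j - 1, u]
                table[i, j, u] = a + b
    return table[n1, n2]


def _exact_p_no_ties(u_obs: float, n1: int, n2: int) -> float:
    counts = _exact_u_sf_counts(n1, n2)
    total = counts.sum()
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    us = np.arange(n1 * n2 + 1)
    # tiny slack keeps float comparison faithful to the integer lattice
    return float(counts[np.abs(us - mu) >= dev - 1e-9].sum() / total)


def _exact_p_with_ties(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by full enumeration of group assignments."""
    n1 = len(x)
    pooled = np.concatenate([x, y])
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    mu = n1 * (n - n1) / 2.0
    r1_obs = ranks[:n1].sum()
    u_obs = r1_obs - n1 * (n1 + 1) / 2.0
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in itertools.combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def mann_whitney(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney U test.

    ``mode="exact"`` enumerates the permutation distribution (a recursion on
    the U distribution when there are no ties; full enumeration of group
    assignments, feasible for n₁+n₂ ≤ 12, when there are ties).
    ``mode="asymptotic"`` uses the tie-corrected normal approximation with
    no continuity correction. ``mode="auto"`` picks exact when n₁+n₂ ≤ 12
    and the pooled sample has no ties, else asymptotic.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("mann_whitney needs both samples nonempty")
    if mode not in ("exact", "asymptotic", "auto"):
        raise ConfigError(f"unknown mode {mode!r}")
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n
    u1, var = _u_from_midranks(x, y)

    if np.all(pooled == pooled[0]):
        return TestResult("mw_exact" if mode == "exact" else "mw_asymptotic",
                          u1, 1.0,
                          warnings=["degenerate data: all values identical"])

    if mode == "auto":
        mode = "exact" if (n <= 12 and not has_ties) else "asymptotic"

    if mode == "exact":
        if has_ties:
            if n > 12:
                raise ConfigError(
                    "exact mode with ties enumerates all assignments and is "
                    f"limited to n1+n2 <= 12 (got {n})"
                )
            p = _exact_p_with_ties(x, y)
        else:
            p = _exact_p_no_ties(u1, n1, n2)
        return TestResult("mw_exact", u1, min(1.0, p))

    z = (u1 - n1 * n2 / 2.0) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult("mw_asymptotic", u1, min(1.0, float(p)))


# ---------------------------------------------------------------------------
# Summaries, dichotomization, odds ratio


def median_iqr(values, convention: str = "linear") -> tuple[float, float, float]:
    """(median, Q1, Q3). ``convention``: ``"linear"`` interpolation (default)
    or ``"haverage"`` (the (n+1)p weighted-average rule SPSS reports)."""
    v = np.asarray(values, dtype=float).ravel()
    if len(v) == 0:
        raise ValidationError("median_iqr needs at least one value")
    method = {"linear": "linear", "haverage": "weibull"}.get(convention)
    if method is None:
        raise ConfigError(f"unknown quartile convention {convention!r}")
    q1, med, q3 = np.percentile(v, [25, 50, 75], method=method)
    return float(med), float(q1), float(q3)


def dichotomize(values, rule="median") -> np.ndarray:
    """Split values into ``"low"`` (< cut) and ``"high"`` (≥ cut) labels.

    ``rule="median"`` uses the sample median as the cut; ties at the cut go
    to "high". A numeric ``rule`` is used as an explicit threshold.
    """
    v = np.asarray(values, dtype=float).ravel()
    if isinstance(rule, str):
        if rule != "median":
            raise ConfigError(f"unknown dichotomization rule {rule!r}")
        if len(v) < 2:
            raise ValidationError("median split needs at least two values")
        cut = float(np.median(v))
        if np.all(v == v[0]):
            raise ValidationError("median split impossible: all values equal")
    else:
        cut = float(rule)
    return np.where(v < cut, "low", "high")


def univariate_or(
    predictor,
    outcome,
    *,
    predictor_positive="high",
    outcome_positive=True,
    split_rule: str = "median",
) -> OrResult:
    """Odds ratio of a binary outcome for a binary predictor.

    With the 2×2 cross-tabulation a = (pred⁺, out⁺), b = (pred⁺, out⁻),
    c = (pred⁻, out⁺), d = (pred⁻, out⁻): OR = ad/bc, 95% Wald CI
    exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)), p from the Wald z. Any zero cell
    triggers the Haldane–Anscombe +0.5 correction on all cells (flagged).
    """
    pred = np.asarray(predictor).ravel()
    out = np.asarray(outcome).ravel()
    if len(pred) != len(out):
        raise ValidationError("predictor and outcome lengths differ")
    p_pos = pred == predictor_positive
    o_pos = out == outcome_positive
    if o_pos.all() or (~o_pos).all():
        raise ValidationError("outcome is constant: odds ratio undefined")
    if p_pos.all() or (~p_pos).all():
        raise ValidationError("predictor has a single level")
    a = int((p_pos & o_pos).sum())
    b = int((p_pos & ~o_pos).sum())
    c = int((~p_pos & o_pos).sum())
    d = int((~p_pos & ~o_pos).sum())
    return odds_ratio_2x2(np.array([[a, b], [c, d]]), split_rule=split_rule)


def odds_ratio_2x2(table, *, split_rule: str = "") -> OrResult:
    """OR with Wald CI from an explicit [[a,b],[c,d]] table (see
    :func:`univariate_or`)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError("odds ratio needs a 2x2 table")
    corrected = bool((t == 0).any())
    if corrected:
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    p = 2.0 * sps.norm.sf(abs(z))
    return OrResult(math.exp(log_or), math.exp(log_or - 1.96 * se),
                    math.exp(log_or + 1.96 * se), float(p), split_rule,
                    corrected=corrected, table=np.asarray(table, dtype=np.int64))


# ---------------------------------------------------------------------------
# ROC


def _roc_points(scores: np.ndarray, labels: np.ndarray):
    """Operating points (threshold, sens, spec) for the rule score ≥ t."""
    thresholds = np.unique(scores)[::-1]
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    points = []
    for t in thresholds:
        pred = scores >= t
        sens = float((pred & labels).sum() / n_pos)
        spec = float((~pred & ~labels).sum() / n_neg)
        points.append((float(t), sens, spec))
    return points


def _auc_trapezoid(points) -> float:
    # ROC path from (0,0) through (1-spec, sens) points to (1,1)
    xs = [0.0] + [1.0 - spec for _, _, spec in points] + [1.0]
    ys = [0.0] + [sens for _, sens, _ in points] + [1.0]
    return float(np.trapezoid(ys, xs))


def _auc_concordance(scores: np.ndarray, labels: np.ndarray) -> float:
    pos = scores[labels]
    neg = scores[~labels]
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum()) / diff.size)


def roc_curve(scores, labels) -> RocResult:
    """Empirical ROC of a score for a binary label (positive = True).

    The trapezoidal AUC is cross-checked against the concordance identity
    AUC = (concordant + ½·tied pairs)/(n₊·n₋); a mismatch raises. If the raw
    AUC is below 0.5 the score is negated (flag recorded) so the reported
    curve reads in the conventional orientation. The Youden-optimal point
    maximizes sensitivity + specificity − 1, ties broken by higher
    specificity.
    """
    s = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(labels).ravel().astype(bool)
    if len(s) != len(y):
        raise ValidationError("scores and labels lengths differ")
    if y.all() or (~y).all():
        raise ValidationError("ROC needs both classes present")

    flipped = _auc_concordance(s, y) < 0.5
    if flipped:
        s = -s
    points = _roc_points(s, y)
    auc = _auc_trapezoid(points)
    auc_u = _auc_concordance(s, y)
    if abs(auc - auc_u) > 1e-10:
        raise AssertionError(
            f"trapezoidal AUC {auc} disagrees with concordance AUC {auc_u}"
        )
    best = max(points, key=lambda p: (p[1] + p[2] - 1.0, p[2]))
    return RocResult(points, auc, best[0], best[1], best[2], flipped)
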