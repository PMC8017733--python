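"""Association and comparison tests, implemented from first principles.

The tests a baseline-characteristics table and a paired-classifier analysis
need: Fisher's exact test (point-probability two-sided), Pearson chi-square,
McNemar's paired test (exact binomial below a discordant-count threshold,
chi-square above), Mann-Whitney U (exact enumeration for small samples,
tie-corrected continuity-corrected normal approximation otherwise), Student
and Welch t-tests (raw data or published summary statistics) and a binary
logistic regression fitted by iteratively reweighted least squares whose
linear predictor serves as a combined score for downstream ROC analysis.

Only probability distribution functions are delegated to scipy; the test
statistics, enumeration logic and the IRLS loop are implemented here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import CohortTable
from .scores import ScorePanel

__all__ = [
    "Table2x2", "LogisticFit", "McNemarResult", "GramCrosstab",
    "fisher_exact", "chi_square", "mcnemar", "mann_whitney",
    "t_test", "t_test_from_stats", "logistic_fit", "gram_crosstab",
]


@dataclass(frozen=True)
class Table2x2:
    """2x2 contingency table: rows = groups, columns = outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def _log_hypergeom_pmf(k: int, row1: int, col1: int, total: int) -> float:
    """log P(X = k) for X ~ Hypergeom(total, col1, row1) via lgamma."""
    def lchoose(n, r):
        if r < 0 or r > n:
            return -math.inf
        return math.lgamma(n + 1) - math.lgamma(r + 1) - math.lgamma(n - r + 1)
    return lchoose(col1, k) + lchoose(total - col1, row1 - k) - lchoose(total, row1)


def fisher_exact(table: Table2x2, method: str = "point_probability") -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    ``point_probability`` (default) sums the hypergeometric probabilities of
    all tables with the observed margins whose point probability does not
    exceed the observed table's. ``doubled_one_tail`` doubles the smaller
    exact tail (capped at 1).
    """
    row1 = table.a + table.b
    col1 = table.a + table.c
    total = table.a + table.b + table.c + table.d
    k_min = max(0, row1 + col1 - total)
    k_max = min(row1, col1)
    logp = np.array([_log_hypergeom_pmf(k, row1, col1, total)
                     for k in range(k_min, k_max + 1)])
    pmf = np.exp(logp - logp.max())
    pmf /= pmf.sum()
    obs = table.a - k_min
    if method == "point_probability":
        p = float(pmf[pmf <= pmf[obs] * (1 + 1e-7)].sum())
    elif method == "doubled_one_tail":
        lower = float(pmf[: obs + 1].sum())
        upper = float(pmf[obs:].sum())
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown method {method!r}")
    return min(p, 1.0)


def chi_square(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of independence on an r x c table.

    ``correction`` applies the Yates continuity correction (2x2 only).
    Returns (statistic, p) against chi-square with (r-1)(c-1) df.
    """
    obs = table.as_array() if isinstance(table, Table2x2) else np.asarray(table, dtype=float)
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if total <= 0:
        raise ValueError("table total must be positive")
    expected = row @ col / total
    if (expected == 0).any():
        raise ValueError("zero marginal: chi-square undefined")
    diff = np.abs(obs - expected)
    if correction:
        if obs.shape != (2, 2):
            raise ValueError("Yates correction applies to 2x2 tables only")
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return statistic, float(stats.chi2.sf(statistic, df))


@dataclass(frozen=True)
class McNemarResult:
    p: float
    method: str                   # "exact" | "chi2"
    statistic: Optional[float]    # chi-square statistic when asymptotic


def mcnemar(b_discordant: int, c_discordant: int, exact_threshold: int = 25) -> McNemarResult:
    """McNemar's paired test on the two discordant counts.

    Exact two-sided binomial p when b + c < ``exact_threshold`` (doubled
    smaller tail of Binomial(b+c, 1/2), capped at 1); otherwise the
    chi-square approximation (b - c)^2 / (b + c) with 1 df.
    """
    b, c = b_discordant, c_discordant
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    n = b + c
    if n == 0:
        return McNemarResult(p=1.0, method="exact", statistic=None)
    if n < exact_threshold:
        tail = min(_binom_cdf(min(b, c), n), 1.0)
        return McNemarResult(p=min(1.0, 2.0 * tail), method="exact", statistic=None)
    statistic = (b - c) ** 2 / n
    return McNemarResult(p=float(stats.chi2.sf(statistic, 1)), method="chi2",
                         statistic=float(statistic))


def _binom_cdf(k: int, n: int) -> float:
    """P(X <= k) for X ~ Binomial(n, 1/2), by direct summation."""
    total = 0.0
    for i in range(k + 1):
        total += math.exp(math.lgamma(n + 1) - math.lgamma(i + 1)
                          - math.lgamma(n - i + 1) - n * math.log(2))
    return total


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U of x over y with ties counted one half."""
    ranks = stats.rankdata(np.concatenate([x, y]))
    rx = ranks[: len(x)].sum()
    return rx - len(x) * (len(x) + 1) / 2.0


def mann_whitney(x, y, exact_limit: int = 12) -> tuple[float, float, str]:
    """Mann-Whitney U test; returns (U, two-sided p, method).

    For n + m <= ``exact_limit`` the p-value is computed by enumerating all
    group assignments of the pooled sample (valid under ties); otherwise a
    tie-corrected, continuity-corrected normal approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    mean_u = n * m / 2.0

    if n + m <= exact_limit:
        pooled = np.concatenate([x, y])
        dev_obs = abs(u - mean_u)
        count = total = 0
        for combo in itertools.combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(combo)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - mean_u) >= dev_obs - 1e-12:
                count += 1
        return u, count / total, "exact"

    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    big_n = n + m
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (big_n * (big_n - 1))
    var_u = n * m / 12.0 * ((big_n + 1) - tie_term)
    if var_u <= 0:
        return u, 1.0, "normal"
    z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    return u, float(2 * stats.norm.sf(z)), "normal"


def t_test(x, y, welch: bool = False) -> tuple[float, float]:
    """Two-sample t-test on raw data; returns (t, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return t_test_from_stats(x.mean(), x.std(ddof=1), len(x),
                             y.mean(), y.std(ddof=1), len(y), welch=welch)


def t_test_from_stats(mean1: float, sd1: float, n1: int,
                      mean2: float, sd2: float, n2: int,
                      welch: bool = False) -> tuple[float, float]:
    """Two-sample t-test from summary statistics (mean, SD, n) per group.

    Published tables often report only summaries; Student's pooled-variance
    form is the default, Welch's unequal-variance form optional.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 observations per group")
    v1, v2 = sd1 ** 2, sd2 ** 2
    if welch:
        se2 = v1 / n1 + v2 / n2
        df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1 / n1 + 1 / n2)
        df = n1 + n2 - 2
    if se2 == 0:
        return 0.0, 1.0
    t = (mean1 - mean2) / math.sqrt(se2)
    return float(t), float(2 * stats.t.sf(abs(t), df))


@dataclass
class LogisticFit:
    """Binary logistic regression result (log-odds scale)."""

    intercept: float
    coef: np.ndarray
    converged: bool
    n_iter: int
    linear_predictor: np.ndarray   # per-record combined score
    loglik: float
    loglik_path: list[float] = field(default_factory=list)
    message: str = ""

    def predict_linear(self, predictors) -> np.ndarray:
        X = np.asarray(predictors, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept + X @ self.coef


def logistic_fit(outcome, predictors, tol: float = 1e-8, max_iter: int = 25) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS (Newton-Raphson).

    ``outcome`` is 0/1 per record; ``predictors`` is (n,) or (n, k).
    Convergence: max |score| (gradient of the log-likelihood) below ``tol``.
    Perfect separation shows up as non-convergence with drifting coefficients;
    the fit is flagged and the last iterate returned.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.shape[0] != X.shape[0]:
        raise ValueError("outcome and predictors must be aligned")
    if np.unique(y).size < 2:
        raise ValueError("outcome must take both values 0 and 1")
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    loglik_path: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        loglik_path.append(float((y * np.log(mu + 1e-300)
                                  + (1 - y) * np.log(1 - mu + 1e-300)).sum()))
        score = Xd.T @ (y - mu)
        if np.abs(score).max() < tol:
            converged = True
            break
        w = np.clip(mu * (1 - mu), 1e-10, None)
        hessian = Xd.T @ (Xd * w[:, None])
        try:
            step = np.linalg.solve(hessian, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
    eta = Xd @ beta
    if converged and np.abs(eta).max() > 20:
        # fitted probabilities numerically 0/1: the gradient vanishes on a
        # divergent path, not at an interior maximum
        converged = False
        message = ("fitted probabilities numerically 0 or 1; "
                   "possible complete separation")
    elif converged:
        message = ""
    else:
        message = "did not converge within max_iter; possible quasi-complete separation"
    return LogisticFit(
        intercept=float(beta[0]), coef=beta[1:], converged=converged,
        n_iter=n_iter, linear_predictor=eta, loglik=loglik_path[-1],
        loglik_path=loglik_path, message=message,
    )


@dataclass(frozen=True)
class GramCrosstab:
    """Rule-agreement partition of culture-positive patients and the
    Gram-stain cross-tabulation of isolates in the discordant cells."""

    venn: dict                      # both / only_nlcr / only_mss / neither patient counts
    n_evaluable: int                # culture positives with both scores evaluable
    gram_table: Optional[Table2x2]  # rows: only_nlcr, only_mss; cols: gram-neg, gram-pos
    fisher_p: Optional[float]
    message: str = ""


def gram_crosstab(cohort: CohortTable, panels: Sequence[ScorePanel],
                  nlcr_cut: float = 12.0, mss_cut: int = 3) -> GramCrosstab:
    """Partition true positives by which rule predicted them; compare the
    Gram-stain mix of the isolates flagged by only one rule.

    Patients are partitioned (complete-case on both scores); the Gram table
    counts *isolates* (a culture can grow more than one organism), which is
    why its totals can exceed the patient counts.
    """
    if len(cohort) != len(panels):
        raise ValueError("cohort and panels must be aligned")
    venn = {"both": 0, "only_nlcr": 0, "only_mss": 0, "neither": 0}
    gram = {"only_nlcr": [0, 0], "only_mss": [0, 0]}  # [gram-negative, gram-positive]
    n_eval = 0
    for record, panel in zip(cohort, panels):
        if not record.culture_positive or panel.nlcr is None:
            continue
        n_eval += 1
        nlcr_hit = panel.nlcr > nlcr_cut
        mss_hit = panel.mss_points >= mss_cut
        cell = ("both" if nlcr_hit and mss_hit else
                "only_nlcr" if nlcr_hit else
                "only_mss" if mss_hit else "neither")
        venn[cell] += 1
        if cell in gram:
            for pathogen in record.pathogens:
                gram[cell][0 if pathogen.gram == "negative" else 1] += 1
    if sum(gram["only_nlcr"]) == 0 or sum(gram["only_mss"]) == 0:
        return GramCrosstab(venn=venn, n_evaluable=n_eval, gram_table=None,
                            fisher_p=None,
                            message="a discordant cell is empty; Gram comparison skipped")
    table = Table2x2(a=gram["only_nlcr"][0], b=gram["only_nlcr"][1],
                     c=gram["only_mss"][0], d=gram["only_mss"][1])
    return GramCrosstab(venn=venn, n_evaluable=n_eval, gram_table=table,
                        fisher_p=fisher_exact(table))
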