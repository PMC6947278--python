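"""The study's statistical battery over cohort tables.

Nonparametric throughout: Shapiro-Wilk normality screening, Mann-Whitney U
between groups, Pearson chi-square for categorical demographics, Friedman
across visits within eyes, pairwise Wilcoxon signed-rank with Bonferroni
correction, Lin's concordance correlation coefficient (CCC) for
interobserver agreement, and Spearman's rho for metric-vs-thickness
correlation.  Distributional machinery is delegated to scipy.stats; Lin's
CCC and its z-transform confidence interval are computed here.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats as sps


class DegenerateSampleError(ValueError):
    """Raised when a test's input admits no sampling distribution."""


@dataclasses.dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: tuple[int, ...]
    adjusted: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def shapiro_wilk(values) -> TestResult:
    """Shapiro-Wilk test of departure from normality (n >= 3)."""
    x = np.asarray(values, float)
    if len(x) < 3:
        raise DegenerateSampleError("Shapiro-Wilk needs n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("constant sample")
    res = sps.shapiro(x)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "shapiro-wilk", (len(x),))


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact null enumeration for small samples (n1 + n2 <= 12, no ties),
    normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise DegenerateSampleError("both samples must be nonempty")
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(float(res.statistic), float(res.pvalue),
                      f"mann-whitney-{method}", (len(x), len(y)))


def pearson_chi_square(table, correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 contingency table (1 df).

    No Yates continuity correction by default; ``correction=True`` enables
    it.  Zero marginals are rejected.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise DegenerateSampleError("zero marginal in contingency table")
    chi2, p, dof, expected = sps.chi2_contingency(t, correction=correction)
    if np.any(expected <= 0):
        raise DegenerateSampleError("expected count of zero")
    return TestResult(float(chi2), float(p), "pearson-chi2", (int(t.sum()),))


def friedman(block_matrix) -> TestResult:
    """Friedman rank test on an eyes x visits block matrix (complete blocks)."""
    m = np.asarray(block_matrix, float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise DegenerateSampleError("need >= 2 eyes and >= 2 visits")
    if not np.all(np.isfinite(m)):
        raise DegenerateSampleError("incomplete blocks are not imputed")
    if np.all(m == m[:, :1]):
        # identical values across visits: zero statistic by convention
        return TestResult(0.0, 1.0, "friedman", m.shape)
    res = sps.friedmanchisquare(*(m[:, j] for j in range(m.shape[1])))
    return TestResult(float(res.statistic), float(res.pvalue), "friedman", m.shape)


def wilcoxon_signed_rank(x, y) -> TestResult:
    """Two-sided Wilcoxon signed-rank on paired samples; zeros dropped."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    d = x - y
    if np.all(d == 0):
        raise DegenerateSampleError("all paired differences are zero")
    res = sps.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided",
                       mode="auto")
    return TestResult(float(res.statistic), float(res.pvalue),
                      "wilcoxon-signed-rank", (len(x),))


def bonferroni(results: list[TestResult], m: int | None = None) -> list[TestResult]:
    """Bonferroni adjustment: p_adj = min(1, m * p_raw)."""
    m = m if m is not None else len(results)
    return [dataclasses.replace(r, p_value=min(1.0, m * r.p_value), adjusted=True)
            for r in results]


def wilcoxon_bonferroni(pairs: list[tuple]) -> list[TestResult]:
    """Signed-rank tests for several time-point contrasts, jointly corrected."""
    return bonferroni([wilcoxon_signed_rank(x, y) for x, y in pairs])


def lin_ccc(x, y, alpha: float = 0.05) -> tuple[float, float, float]:
    """Lin's concordance correlation coefficient with its (1-alpha) CI.

    ccc = 2 cov(x, y) / (var x + var y + (mean x - mean y)^2), using
    population (1/n) moments.  The confidence interval is computed on the
    Fisher z-transform of the coefficient with Lin's asymptotic variance,
    then mapped back with tanh.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n != len(y) or n < 3:
        raise DegenerateSampleError("need paired samples of length >= 3")
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population moments
    if vx == 0 and vy == 0:
        raise DegenerateSampleError("both samples constant")
    cov = float(np.mean((x - mx) * (y - my)))
    ccc = 2 * cov / (vx + vy + (mx - my) ** 2)

    if abs(ccc) >= 1.0 - 1e-15:
        return float(ccc), float(ccc), float(ccc)
    r = cov / math.sqrt(vx * vy) if vx > 0 and vy > 0 else 0.0
    u = (mx - my) / (vx * vy) ** 0.25 if vx > 0 and vy > 0 else 0.0
    z = math.atanh(ccc)
    if abs(r) < 1e-15:
        se_z = 1.0 / math.sqrt(n - 2)
    else:
        se_z2 = ((1 - r**2) * ccc**2 / ((1 - ccc**2) * r**2)
                 + 2 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - ccc**2) ** 2)
                 - ccc**4 * u**4 / (2 * r**2 * (1 - ccc**2) ** 2)) / (n - 2)
        se_z = math.sqrt(max(se_z2, 0.0))
    q = sps.norm.ppf(1 - alpha / 2)
    return float(ccc), float(math.tanh(z - q * se_z)), float(math.tanh(z + q * se_z))


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation (mid-ranks), p by t-approximation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise DegenerateSampleError("need paired samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateSampleError("constant input has no rank correlation")
    res = sps.spearmanr(x, y)
    return TestResult(float(res.statistic), float(res.pvalue),
                      "spearman", (len(x),))


# ---------------------------------------------------------------------------
# battery over a long-format cohort table


def _cell(df: pd.DataFrame, **sel) -> pd.DataFrame:
    out = df
    for k, v in sel.items():
        out = out[out[k] == v]
    return out


def between_group_tests(df: pd.DataFrame, visit: str = "baseline",
                        groups: tuple[str, str] = ("iERM", "control")) -> pd.DataFrame:
    """Mann-Whitney per (region, metric) between the two groups at one visit."""
    rows = []
    sub = df[df.visit == visit]
    for (region, metric), cell in sub.groupby(["region", "metric"], sort=True):
        a = cell[cell.group == groups[0]].value.to_numpy()
        b = cell[cell.group == groups[1]].value.to_numpy()
        if len(a) == 0 or len(b) == 0:
            continue
        r = mann_whitney_u(a, b)
        rows.append(dict(comparison=f"{groups[0]}-vs-{groups[1]}", region=region,
                         metric=metric, visit=visit, statistic=r.statistic,
                         p_raw=r.p_value, p_adjusted=np.nan, method=r.method))
    return pd.DataFrame(rows)


def within_group_tests(df: pd.DataFrame, group: str = "iERM") -> pd.DataFrame:
    """Friedman across visits plus pairwise Wilcoxon/Bonferroni, per metric.

    Only metrics observed at >= 2 visits are testable.  Both the omnibus
    p-value and each Bonferroni-adjusted pairwise contrast are reported,
    labelled by method.
    """
    rows = []
    sub = df[(df.group == group)]
    if "grader" in sub.columns:
        sub = sub[sub.grader == sorted(sub.grader.unique())[0]]
    for (region, metric), cell in sub.groupby(["region", "metric"], sort=True):
        visits = [v for v in ("baseline", "1mo", "6mo") if v in set(cell.visit)]
        if len(visits) < 2:
            continue
        wide = cell.pivot(index="eye_id", columns="visit", values="value")[visits]
        wide = wide.dropna()
        fr = friedman(wide.to_numpy())
        rows.append(dict(comparison="across-visits", region=region, metric=metric,
                         visit="|".join(visits), statistic=fr.statistic,
                         p_raw=fr.p_value, p_adjusted=np.nan, method=fr.method))
        contrasts = [(a, b) for i, a in enumerate(visits) for b in visits[i + 1:]]
        raw = [wilcoxon_signed_rank(wide[a].to_numpy(), wide[b].to_numpy())
               for a, b in contrasts]
        adjusted = bonferroni(raw)
        for (a, b), r0, r1 in zip(contrasts, raw, adjusted):
            rows.append(dict(comparison=f"{a}-vs-{b}", region=region,
                             metric=metric, visit=f"{a}|{b}",
                             statistic=r0.statistic, p_raw=r0.p_value,
                             p_adjusted=r1.p_value, method=r0.method))
    return pd.DataFrame(rows)


def interobserver_ccc(df: pd.DataFrame) -> pd.DataFrame:
    """Lin's CCC between the two graders, per (region, metric)."""
    rows = []
    graders = sorted(df.grader.unique())
    if len(graders) != 2:
        raise DegenerateSampleError("CCC needs exactly two graders")
    key = ["eye_id", "region", "metric", "visit"]
    wide = df.pivot_table(index=key, columns="grader", values="value").reset_index()
    for (region, metric), cell in wide.groupby(["region", "metric"], sort=True):
        ccc, lo, hi = lin_ccc(cell[graders[0]].to_numpy(),
                              cell[graders[1]].to_numpy())
        rows.append(dict(region=region, metric=metric, ccc=ccc,
                         ci_low=lo, ci_high=hi, n=len(cell)))
    return pd.DataFrame(rows)


def summarize_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Mean ± SD per (group, region, metric, visit) cell."""
    g = df.groupby(["group", "region", "metric", "visit"], sort=True).value
    out = g.agg(["mean", "std", "count"]).reset_index()
    return out.rename(columns={"count": "n", "std": "sd"})
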