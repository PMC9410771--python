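"""Statistical battery over per-axon pulse-spread results.

Each axon is an independent replicate. Groups are screened for normality
(Shapiro-Wilk); because the measures are non-normal, omnibus comparisons use
Kruskal-Wallis with post hoc Mann-Whitney pairwise tests corrected within each
measure family by Benjamini-Hochberg; anterograde bias is tested per group
with a two-sided Wilcoxon signed-rank test against 50%; relationships with
axon diameter use Pearson correlation with an OLS slope and 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "normality_screen",
    "omnibus_and_pairwise",
    "bias_test",
    "diameter_correlation",
    "results_table",
]

ALPHA = 0.05


@dataclass
class TestResult:
    test: str
    comparison: str
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    n: tuple[int, ...] = ()
    flag: str = ""

    def significant(self, alpha: float = ALPHA) -> bool:
        p = self.p_adjusted if self.p_adjusted is not None else self.p_raw
        return p <= alpha


def results_table(results: list[TestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = asdict(r)
        d["n"] = "/".join(str(x) for x in r.n)
        rows.append(d)
    return pd.DataFrame(rows)


def normality_screen(groups: dict[str, np.ndarray]) -> list[TestResult]:
    """Shapiro-Wilk W and p per group; groups with n < 3 or zero variance are flagged."""
    out = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 3:
            out.append(TestResult("shapiro", name, float("nan"), float("nan"), n=(len(vals),), flag="n<3"))
            continue
        if np.ptp(vals) == 0:
            out.append(TestResult("shapiro", name, float("nan"), float("nan"), n=(len(vals),), flag="constant"))
            continue
        W, p = sps.shapiro(vals)
        out.append(TestResult("shapiro", name, float(W), float(p), n=(len(vals),)))
    return out


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact when both n <= 25 with no ties, asymptotic with tie correction otherwise."""
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) <= 25 and len(y) <= 25 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def omnibus_and_pairwise(
    groups: dict[str, np.ndarray], family: str = ""
) -> list[TestResult]:
    """Kruskal-Wallis omnibus followed by all pairwise Mann-Whitney tests.

    Pairwise p-values are Benjamini-Hochberg adjusted within this family of
    comparisons. With all values tied across groups the omnibus returns H = 0,
    p = 1 rather than erroring.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if any(len(a) < 1 for a in arrays):
        raise ValueError("every group needs >= 1 value")

    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        omni = TestResult("kruskal-wallis", family or "omnibus", 0.0, 1.0, n=tuple(len(a) for a in arrays), flag="all tied")
    else:
        H, p = sps.kruskal(*arrays)
        omni = TestResult("kruskal-wallis", family or "omnibus", float(H), float(p), n=tuple(len(a) for a in arrays))

    pair_results = []
    for (i, j) in combinations(range(len(names)), 2):
        U, p = _mannwhitney(arrays[i], arrays[j])
        pair_results.append(
            TestResult(
                "mann-whitney",
                f"{names[i]} vs {names[j]}",
                U,
                p,
                n=(len(arrays[i]), len(arrays[j])),
            )
        )
    if pair_results:
        praw = [r.p_raw for r in pair_results]
        _, padj, _, _ = multipletests(praw, alpha=ALPHA, method="fdr_bh")
        for r, pa in zip(pair_results, padj):
            r.p_adjusted = float(pa)
    return [omni, *pair_results]


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Step-up adjusted p-values (thin wrapper kept for the arithmetic oracle)."""
    _, padj, _, _ = multipletests(np.asarray(p_values, float), method="fdr_bh")
    return padj


def bias_test(percent_anterograde: np.ndarray, comparison: str = "") -> TestResult:
    """Two-sided Wilcoxon signed-rank test of percent anterograde against 50%.

    Exact for n <= 25 without ties or zeros. All values exactly at 50 give
    p = 1 (no evidence of bias).
    """
    vals = np.asarray(percent_anterograde, dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) < 1:
        raise ValueError("need >= 1 value")
    diffs = vals - 50.0
    if np.all(diffs == 0):
        return TestResult("wilcoxon-signed-rank", comparison, 0.0, 1.0, n=(len(vals),), flag="all at 50")
    nz = diffs[diffs != 0]
    no_ties = len(np.unique(np.abs(nz))) == len(nz)
    method = "exact" if (len(nz) <= 25 and no_ties) else "approx"
    res = sps.wilcoxon(diffs, alternative="two-sided", method=method, zero_method="wilcox")
    return TestResult("wilcoxon-signed-rank", comparison, float(res.statistic), float(res.pvalue), n=(len(vals),))


def diameter_correlation(
    measures: dict[str, np.ndarray], diameters: np.ndarray
) -> list[TestResult]:
    """Pearson r (+ OLS slope with 95% CI) of each measure against axon diameter."""
    import statsmodels.api as sm

    d = np.asarray(diameters, dtype=float)
    if len(d) < 3:
        raise ValueError("need >= 3 axons")
    if np.any(d <= 0):
        raise ValueError("diameters must be > 0")
    if np.ptp(d) == 0:
        raise ValueError("zero-variance diameters")
    out = []
    for name, vals in measures.items():
        v = np.asarray(vals, dtype=float)
        ok = ~np.isnan(v)
        if np.ptp(v[ok]) == 0:
            raise ValueError(f"zero-variance measure {name}")
        r, p = sps.pearsonr(d[ok], v[ok])
        fit = sm.OLS(v[ok], sm.add_constant(d[ok])).fit()
        lo, hi = fit.conf_int(alpha=0.05)[1]
        res = TestResult("pearson", f"{name} vs diameter", float(r), float(p), n=(int(ok.sum()),))
        res.flag = f"slope={fit.params[1]:.4g} ci95=({lo:.4g},{hi:.4g})"
        out.append(res)
    return out
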