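"""Group-comparison statistics across omics layers.

Welch t for numeric features (methylation-style), two-sided Fisher exact
for binary features (mutation/CNV flags), Benjamini-Hochberg / Bonferroni
multiplicity corrections, Pearson/Spearman correlation, and the drug
IC50-vs-index association screen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class AssocError(ValueError):
    pass


def welch_t(x, y) -> tuple[float, float, float]:
    """Two-sided Welch t-test: returns (t, Satterthwaite df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if x.size < 2 or y.size < 2:
        raise AssocError("each group needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise AssocError("both groups have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    se2x, se2y = vx / x.size, vy / y.size
    df = (se2x + se2y) ** 2 / (
        se2x**2 / (x.size - 1) + se2y**2 / (y.size - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    P-value by the probability-mass rule (sum of hypergeometric
    probabilities not exceeding that of the observed table).  The reported
    odds ratio is the sample cross-product ratio, with a Haldane-Anscombe
    0.5 continuity correction applied for display only when a zero cell
    exists; the p-value never uses the correction.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape != (2, 2):
        raise AssocError("table must be 2x2")
    if np.any(tab < 0) or not np.allclose(tab, np.round(tab)):
        raise AssocError("table must hold non-negative integers")
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise AssocError("zero margin")
    a, b, c, d = tab.ravel()
    if b * c > 0:
        odds = (a * d) / (b * c)
    else:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    p = float(stats.fisher_exact(np.round(tab).astype(int), alternative="two-sided")[1])
    return float(odds), min(p, 1.0)


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment.

    ``bh``: Benjamini-Hochberg step-up with monotonicity enforcement;
    ``bonferroni``: ``min(1, m*p)``.  Output order matches input order.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise AssocError("p-values must lie in [0, 1]")
    m = p.size
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method != "bh":
        raise AssocError(f"unknown correction {method!r}")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def correlate(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient with two-sided p (t approximation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise AssocError("need aligned vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AssocError("zero-variance input")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise AssocError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class FeatureComparison:
    feature_id: str
    effect: float
    statistic: float
    p: float
    p_adj: float
    method: str

    @property
    def significant(self) -> bool:
        return self.p_adj < 0.05


def group_feature_screen(
    features: pd.DataFrame,
    groups,
    test: str = "welch",
    correction: str = "bh",
    log_scale: bool = False,
) -> list[FeatureComparison]:
    """Per-feature low-vs-high comparison between MAA groups.

    ``features`` is samples x features; ``groups`` aligns with its rows and
    holds ``below``/``above`` labels.  Numeric features use Welch t on the
    log2(x+1) scale unless ``log_scale`` says values are already logged;
    binary features use Fisher exact.  Effects are mean differences
    (below - above) for Welch and frequency differences for Fisher.
    """
    g = np.asarray(groups)
    if set(np.unique(g)) - {"below", "above"}:
        raise AssocError("groups must be 'below'/'above' labels")
    if len(g) != len(features):
        raise AssocError("groups must align with feature rows")
    lo = g == "below"
    hi = g == "above"
    if test not in ("welch", "fisher"):
        raise AssocError(f"unknown test {test!r}")

    vals = features.to_numpy(dtype=float)
    is_binary = np.isin(vals[np.isfinite(vals)], (0.0, 1.0)).all()
    if test == "fisher" and not is_binary:
        raise AssocError("fisher screen requires binary features")
    if test == "welch" and is_binary and vals.size:
        logger.warning("welch screen on binary-looking features")

    rows: list[tuple[str, float, float, float]] = []
    for col in features.columns:
        v = features[col].to_numpy(dtype=float)
        if test == "welch":
            x = v[lo]
            y = v[hi]
            if log_scale:
                xs, ys = x, y
            else:
                xs, ys = np.log2(x + 1.0), np.log2(y + 1.0)
            try:
                t, _, p = welch_t(xs, ys)
            except AssocError:
                logger.warning("feature %s skipped (zero variance)", col)
                continue
            eff = float(np.nanmean(xs) - np.nanmean(ys))
            rows.append((str(col), eff, t, p))
        else:
            ok = np.isfinite(v)
            tab = [
                [int(np.sum((v == 1) & lo & ok)), int(np.sum((v == 0) & lo & ok))],
                [int(np.sum((v == 1) & hi & ok)), int(np.sum((v == 0) & hi & ok))],
            ]
            try:
                odds, p = fisher_exact(tab)
            except AssocError:
                logger.warning("feature %s skipped (degenerate table)", col)
                continue
            f_lo = tab[0][0] / max(tab[0][0] + tab[0][1], 1)
            f_hi = tab[1][0] / max(tab[1][0] + tab[1][1], 1)
            rows.append((str(col), f_lo - f_hi, odds, p))

    if not rows:
        return []
    p_adj = adjust_pvalues([r[3] for r in rows], method=correction)
    return [
        FeatureComparison(
            feature_id=fid,
            effect=eff,
            statistic=stat,
            p=p,
            p_adj=float(pa),
            method=f"{test}+{correction}",
        )
        for (fid, eff, stat, p), pa in zip(rows, p_adj)
    ]


def screen_to_frame(results: list[FeatureComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "effect": [r.effect for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p for r in results],
            "p_adj": [r.p_adj for r in results],
            "significant": [int(r.significant) for r in results],
            "method": [r.method for r in results],
        }
    )


def drug_sensitivity_assoc(
    ic50: pd.DataFrame,
    maa: pd.Series,
    threshold: float,
    min_lines: int = 8,
) -> pd.DataFrame:
    """Per-drug association between ln(IC50) and the balance index.

    ``ic50`` is drugs x cell lines (natural-log IC50, NaN = missing);
    ``maa`` maps cell line -> index value.  Per drug: Pearson r with the
    index across lines, and the mean IC50 fold change in low vs high lines
    (``exp(mean ln IC50 low - mean ln IC50 high)``).  Drugs with fewer than
    ``min_lines`` observations or zero variance are skipped with a warning.
    Rows are sorted by |log fold change| descending; p-values are
    BH-adjusted across retained drugs.
    """
    common = [c for c in ic50.columns if c in maa.index]
    rows = []
    for drug in ic50.index:
        v = ic50.loc[drug, common].to_numpy(dtype=float)
        m = maa.loc[common].to_numpy(dtype=float)
        ok = np.isfinite(v) & np.isfinite(m)
        if ok.sum() < min_lines:
            logger.warning("drug %s skipped: %d observations", drug, int(ok.sum()))
            continue
        v, mv = v[ok], m[ok]
        if np.ptp(v) == 0:
            logger.warning("drug %s skipped: zero IC50 variance", drug)
            continue
        r, p = correlate(v, mv, method="pearson")
        low = mv < threshold
        if not low.any() or low.all():
            logger.warning("drug %s skipped: one-sided index split", drug)
            continue
        ln_fc = float(v[low].mean() - v[~low].mean())
        rows.append((str(drug), r, p, np.exp(ln_fc), ln_fc, int(ok.sum())))
    if not rows:
        return pd.DataFrame(
            columns=["drug", "pearson_r", "p", "fold_change", "ln_fold_change",
                     "n", "p_adj"]
        )
    df = pd.DataFrame(
        rows, columns=["drug", "pearson_r", "p", "fold_change", "ln_fold_change", "n"]
    )
    df["p_adj"] = adjust_pvalues(df["p"].to_numpy(), method="bh")
    return df.reindex(
        df["ln_fold_change"].abs().sort_values(ascending=False).index
    ).reset_index(drop=True)
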