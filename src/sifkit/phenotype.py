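"""Correlating impact scores with quantitative phenotypes.

For the yeast system the phenotype is cell length at septation: fission
yeast grows only in length and divides at mitosis, so length reports the
timing of mitotic entry. Scores and lengths are matched by mutation,
fitted by ordinary least squares, and summarised by the squared Pearson
correlation with a two-tailed p value from the exact t distribution,
``t = r sqrt(n-2) / sqrt(1-r^2)`` — appropriate at the small n of
temperature-sensitive strain panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = ["CorrelationResult", "correlate", "stratify",
           "validate_phenotypes", "match_scores_to_lengths"]


@dataclass(frozen=True)
class CorrelationResult:
    r2: float
    p_two_tailed: float
    n: int
    slope: float
    intercept: float


def validate_phenotypes(df: pd.DataFrame, mean_col, stdev_col):
    if (df[stdev_col] < 0).any():
        raise ValidationError("phenotype stdev must be non-negative")
    if "n" in df.columns and (df["n"] < 1).any():
        raise ValidationError("phenotype n must be >= 1")
    return df


def correlate(scores, phenotypes, *, log_log=False,
              weights=None) -> CorrelationResult:
    """OLS of phenotype on score; r^2 and exact two-tailed p.

    ``scores`` and ``phenotypes`` are matched 1-d sequences. With
    ``log_log`` both sides are log-transformed (requires positive
    values). ``weights`` enables optional inverse-variance weighted
    fitting for exploration; r^2/p always come from the unweighted
    Pearson correlation unless weights are given, in which case the
    weighted correlation is reported.
    """
    x = np.asarray(scores, float)
    y = np.asarray(phenotypes, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("scores and phenotypes must be matched 1-d")
    n = x.size
    if n < 3:
        raise ValidationError(f"need at least 3 matched pairs, got {n}")
    if log_log:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValidationError("log-log correlation needs positive values")
        x, y = np.log(x), np.log(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance in scores or phenotypes")
    if weights is None:
        fit = stats.linregress(x, y)
        r = fit.rvalue
        return CorrelationResult(r2=float(r * r),
                                 p_two_tailed=float(fit.pvalue), n=n,
                                 slope=float(fit.slope),
                                 intercept=float(fit.intercept))
    w = np.asarray(weights, float)
    if w.shape != x.shape or np.any(w <= 0):
        raise ValidationError("weights must be positive and matched")
    w = w / w.sum()
    mx, my = np.sum(w * x), np.sum(w * y)
    cov = np.sum(w * (x - mx) * (y - my))
    vx, vy = np.sum(w * (x - mx) ** 2), np.sum(w * (y - my) ** 2)
    r = cov / np.sqrt(vx * vy)
    slope = cov / vx
    t = r * np.sqrt(n - 2) / np.sqrt(max(1.0 - r * r, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(r2=float(r * r), p_two_tailed=float(p), n=n,
                             slope=float(slope),
                             intercept=float(my - slope * mx))


def stratify(table: pd.DataFrame, impact_class: str,
             class_col="impact_class") -> pd.DataFrame:
    """Subset a matched table to one impact class, preserving order."""
    if impact_class not in ("F", "S"):
        raise ValidationError(
            f"impact_class must be 'F' or 'S', got {impact_class!r}")
    out = table[table[class_col] == impact_class]
    if out.empty:
        raise ValidationError(f"stratum {impact_class!r} is empty")
    return out.reset_index(drop=True)


def match_scores_to_lengths(score_table: pd.DataFrame,
                            lengths: pd.DataFrame,
                            condition="30C") -> pd.DataFrame:
    """Inner-join scored mutations with the cell-length table.

    ``condition`` selects the temperature columns ('25C' or '30C').
    Wild-type rows (no residue change) are dropped; order follows the
    score table.
    """
    mean_col = f"mean_{condition}"
    if mean_col not in lengths.columns:
        raise ValidationError(
            f"no column {mean_col!r}; conditions available: "
            f"{[c[5:] for c in lengths.columns if c.startswith('mean_')]}")
    keep = lengths.dropna(subset=["residue_change"])
    keep = keep[keep["residue_change"] != "NA"]
    merged = score_table.merge(
        keep[["residue_change", mean_col, f"stdev_{condition}"]],
        on="residue_change", how="inner")
    return merged.rename(columns={mean_col: "length",
                                  f"stdev_{condition}": "length_stdev"})
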