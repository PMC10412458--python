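"""Participation polygenic scores and covariate-adjusted association tests.

A participation polygenic score (pPGS) is the weighted sum of an
individual's genotypes over a SNP panel, with the z- (or t-) statistics of
a participation scan as weights (no LD pruning or shrinkage), standardized
to unit variance in the evaluation sample.  Association between the score
and a phenotype is estimated by linear or logistic regression with
caller-supplied covariates; to guard against population stratification the
squared test statistic can be deflated by an LD-score-regression intercept
supplied by the caller (default 1) before the p-value is computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["PgsResult", "compute_pgs", "pgs_association", "group_contrast"]


@dataclass
class PgsResult:
    """Scores plus the association block of one pPGS analysis."""

    scores: np.ndarray
    weights_source: str = ""
    association: dict = field(default_factory=dict)
    intercept_used: float = 1.0


def compute_pgs(genotypes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Per-individual polygenic score, standardized to variance 1.

    Parameters
    ----------
    genotypes:
        Dosage matrix (n_individuals, n_snps) with entries in [0, 2]; NaN
        entries are mean-imputed per SNP.
    weights:
        Per-SNP weights (scan z-statistics); must not be all zero.

    Scores are linear in the weights, so any overall rescaling of the
    weights leaves the standardized scores unchanged.
    """
    g = np.asarray(genotypes, dtype=float)
    w = np.asarray(weights, dtype=float)
    if g.ndim != 2 or w.ndim != 1 or g.shape[1] != w.size:
        raise ValueError("genotypes must be (n, m) and weights length m")
    if not np.any(w != 0):
        raise ValueError("all-zero weights: standardization undefined")
    if np.isnan(g).any():
        col_mean = np.nanmean(g, axis=0)
        idx = np.where(np.isnan(g))
        g = g.copy()
        g[idx] = np.take(col_mean, idx[1])
    raw = g @ w
    sd = raw.std(ddof=0)
    if sd == 0.0:
        raise ValueError("scores are constant; variance-1 standardization undefined")
    return (raw - raw.mean()) / sd


def pgs_association(
    scores: np.ndarray,
    phenotype: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    intercept: float = 1.0,
    family: str = "linear",
) -> dict:
    """Regress a phenotype on the score with covariates; stratification-aware p.

    For quantitative phenotypes (``family="linear"``) an OLS fit of the
    phenotype on [score, covariates, constant]; phenotypes should be
    pre-standardized to variance 1 if effects are to be read in s.d. units.
    For binary phenotypes (``family="logistic"``), a logit fit returning
    log odds ratios.  The p-value divides the squared score statistic by
    ``intercept`` (an LD-score-regression intercept for the phenotype) and
    refers it to a 1-d.f. chi-square.
    """
    y = np.asarray(phenotype, dtype=float)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise ValueError("scores and phenotype must be matching 1-d arrays")
    if intercept <= 0:
        raise ValueError("intercept must be > 0")
    if covariates is None:
        X = s[:, None]
        names = ["pgs"]
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        X = np.column_stack([s, cov])
        names = ["pgs"] + [f"cov{i}" for i in range(cov.shape[1])]
    X = sm.add_constant(X, has_constant="add", prepend=False)
    if y.size <= X.shape[1] + 1:
        raise ValueError("too few observations for the covariate set")

    if family == "linear":
        fit = sm.OLS(y, X).fit()
    elif family == "logistic":
        try:
            fit = sm.Logit(y, X).fit(disp=0)
        except Exception as exc:  # separation or non-convergence
            return {"effect": math.nan, "se": math.nan, "p": math.nan, "n": int(y.size),
                    "flag": f"logistic fit failed: {exc}"}
        if not fit.mle_retvals.get("converged", True):
            return {"effect": float(fit.params[0]), "se": float(fit.bse[0]), "p": math.nan,
                    "n": int(y.size), "flag": "logistic fit did not converge (separation?)"}
    else:
        raise ValueError(f"unknown family {family!r}")

    effect = float(fit.params[0])
    se = float(fit.bse[0])
    stat2 = (effect / se) ** 2 / intercept
    p = float(stats.chi2.sf(stat2, df=1))
    return {"effect": effect, "se": se, "p": p, "n": int(y.size), "flag": ""}


def group_contrast(scores: np.ndarray, group_a: np.ndarray, group_b: np.ndarray) -> dict:
    """Welch comparison of mean standardized score between two disjoint groups.

    ``group_a``/``group_b`` are index arrays into ``scores`` (e.g. sib-pair
    participants vs unrelated participants).  Returns the mean difference
    (a minus b), its standard error, and a two-sided p-value.
    """
    a_idx = np.asarray(group_a)
    b_idx = np.asarray(group_b)
    if np.intersect1d(a_idx, b_idx).size > 0:
        raise ValueError("groups overlap")
    a = np.asarray(scores, dtype=float)[a_idx]
    b = np.asarray(scores, dtype=float)[b_idx]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    diff = float(a.mean() - b.mean())
    se = math.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    res = stats.ttest_ind(a, b, equal_var=False)
    return {
        "diff": diff,
        "se": se,
        "p": float(res.pvalue),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }
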