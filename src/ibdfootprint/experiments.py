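"""Replicated simulation experiments for the sib-pair frequency-ratio curves.

The central design question for the heritability adjustment is how much the
IBD-based frequency contrasts shrink relative to the participant-vs-
population contrast.  These experiments simulate replicated sib-pair
cohorts at a single causal SNP and report the averages over replicates of

    (F_IBD2  - F_IBD0 ) / (F_samp - f_pop)   (between-sib-pair ratio)
    (F_IBD1S - F_IBD1NS) / (F_samp - f_pop)  (within-sib-pair ratio)
    (F_SIBS  - F_SING )  / (F_samp - f_pop)  (sib-pairs vs singletons)

as functions of the sibling recurrence participation rate ratio lambda_S.
Replicate-level aggregation is the mean of per-replicate ratios (the
per-replicate denominator must therefore be estimated precisely, which is
why the default replicate size is in the millions of pairs; see
docs/methods.md for the sensitivity of this choice).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ibdfootprint.cohort_sim import SnpSpec, single_snp_summary
from ibdfootprint.liability import LiabilityModel, liability_corr_for_lambda

__all__ = ["ratio_replicates", "ratio_point", "ratio_curve"]

# Study conditions of the reference experiment: a biobank-like 5.5%
# participation rate, sibling liability correlation reproducing lambda_S = 2,
# and a frequency-0.5 SNP explaining 0.1% of liability variance.
DEFAULT_ALPHA = 0.055
DEFAULT_SIB_CORR = 0.193
DEFAULT_SNP = SnpSpec(f_pop=0.5, var_share=0.001)


def ratio_replicates(
    alpha: float = DEFAULT_ALPHA,
    sib_corr: float = DEFAULT_SIB_CORR,
    snp: SnpSpec = DEFAULT_SNP,
    n_pairs: int = 2_000_000,
    n_reps: int = 100,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Per-replicate frequency ratios for one (alpha, sib_corr) condition.

    Returns a DataFrame with one row per replicate and columns
    ``ratio_bspc``, ``ratio_wspc``, ``ratio_sibs``, ``lambda_s_hat`` and the
    realized participation rate.
    """
    model = LiabilityModel(alpha=alpha, sib_corr=sib_corr, mode=snp.mode)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rows = []
    for child in ss.spawn(n_reps):
        rng = np.random.Generator(np.random.PCG64(child))
        s = single_snp_summary(model, snp, n_pairs, rng)
        rows.append(
            {
                "ratio_bspc": s.ratio_bspc,
                "ratio_wspc": s.ratio_wspc,
                "ratio_sibs": s.ratio_sibs,
                "alpha_realized": s.alpha_realized,
                "lambda_s_hat": (s.n_both / (n_pairs * s.alpha_realized**2))
                if s.alpha_realized > 0
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def ratio_point(
    alpha: float = DEFAULT_ALPHA,
    sib_corr: float = DEFAULT_SIB_CORR,
    snp: SnpSpec = DEFAULT_SNP,
    n_pairs: int = 2_000_000,
    n_reps: int = 100,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.Series:
    """Mean-over-replicates ratios with Monte-Carlo standard errors."""
    df = ratio_replicates(alpha, sib_corr, snp, n_pairs, n_reps, seed)
    out = {}
    for col in ("ratio_bspc", "ratio_wspc", "ratio_sibs", "lambda_s_hat"):
        vals = df[col].dropna()
        out[col] = vals.mean()
        out[col + "_se"] = vals.std(ddof=1) / np.sqrt(len(vals))
    out["n_pairs"] = n_pairs
    out["n_reps"] = n_reps
    return pd.Series(out)


def ratio_curve(
    lambda_grid: np.ndarray | list[float],
    alpha: float = DEFAULT_ALPHA,
    snp: SnpSpec = DEFAULT_SNP,
    n_pairs: int = 1_000_000,
    n_reps: int = 50,
    seed: int | np.random.SeedSequence | None = None,
) -> pd.DataFrame:
    """Ratio curves over a grid of lambda_S values.

    Each lambda_S is converted to the sibling liability correlation that
    produces it (via the bivariate-normal orthant probability) before
    simulating.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rows = []
    for lam, child in zip(lambda_grid, ss.spawn(len(list(lambda_grid)))):
        rho = liability_corr_for_lambda(alpha, lam)
        point = ratio_point(alpha, rho, snp, n_pairs, n_reps, child)
        point["lambda_s"] = lam
        point["sib_corr"] = rho
        rows.append(point)
    return pd.DataFrame(rows)
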