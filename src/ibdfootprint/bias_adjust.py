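"""Major-allele bias modelling and the two-step statistic adjustment.

Genotyping and phasing errors bias the comparisons that split genotypes
into shared and not-shared alleles (TNTC and WSPC) towards the major
allele; the between-sib-pair comparison is immune because it never splits
genotypes.  This module provides

* the closed-form expected bias of the double-heterozygote shared-allele
  call, f*eps(1-f) - (1-f)*eps(f), where eps(f) is the frequency-dependent
  miscall rate of a truly-1 shared allele;
* step one of the adjustment: regression of the t-statistics on centred
  allele frequency cf = f - 1/2 through the origin, keeping the residuals;
* step two: MAF-specific genomic control, dividing the chi-square values
  (from the adjusted t) by a fitted cubic polynomial of MAF and rescaling
  so that the adjusted chi-square values average exactly 1; the final z
  score is the signed square root;
* cross-comparison diagnostics (correlation of t with cf, chi-square
  inflation by MAF stratum, WSPC-vs-BSPC discordance flags).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AdjustmentFit",
    "phasing_bias",
    "make_eps_interpolator",
    "fit_cf_adjustment",
    "maf_genomic_control",
    "two_step_adjust",
    "bias_diagnostics",
]


@dataclass(frozen=True)
class AdjustmentFit:
    """Fitted parameters of the two-step adjustment for one comparison."""

    comparison_label: str = ""
    slope_cf: float = math.nan
    poly_coeffs: tuple[float, ...] = ()
    gc_rescale: float = math.nan


def make_eps_interpolator(freqs: Sequence[float], eps_values: Sequence[float]) -> Callable[[float], float]:
    """Piecewise-linear eps(f) from a tabulated (frequency, rate) curve.

    The double-het miscall rate is estimated empirically (e.g. from trios
    where the other parent resolves the shared allele); no closed form is
    assumed.  Values are clamped to the tabulated range at the ends.
    """
    f = np.asarray(freqs, dtype=float)
    e = np.asarray(eps_values, dtype=float)
    if f.ndim != 1 or f.size != e.size or f.size < 2:
        raise ValueError("need matching 1-d frequency and rate tables with >= 2 points")
    if np.any(np.diff(f) <= 0):
        raise ValueError("frequency grid must be strictly increasing")
    if np.any((e < 0) | (e > 1)):
        raise ValueError("error rates must lie in [0, 1]")

    def eps(x: float) -> float:
        return float(np.interp(x, f, e))

    return eps


def phasing_bias(f: float, eps: Callable[[float], float]) -> float:
    """Expected double-heterozygote bias of the shared-allele frequency.

    At a double-het IBD1 site the truly shared allele is 1 with probability
    1 - f; miscalling 1 as 0 at rate eps(f) and 0 as 1 at rate eps(1 - f)
    biases the called shared-allele frequency by

        f * eps(1 - f) - (1 - f) * eps(f).

    For f > 1/2 the bias is positive (major-allele bias) exactly when
    eps(f)/eps(1 - f) < f/(1 - f).
    """
    if not (0.0 < f < 1.0):
        raise ValueError(f"f must lie in (0, 1); got {f!r}")
    e_f, e_c = eps(f), eps(1.0 - f)
    for name, v in (("eps(f)", e_f), ("eps(1-f)", e_c)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} = {v!r} outside [0, 1]")
    return f * e_c - (1.0 - f) * e_f


def fit_cf_adjustment(
    t_stats: np.ndarray,
    freqs: np.ndarray,
    comparison_label: str = "",
) -> tuple[AdjustmentFit, np.ndarray]:
    """Step one: remove the centred-allele-frequency trend from t-statistics.

    Regresses t on cf = f - 1/2 through the origin and returns the
    residuals.  The slope summarizes the average major-allele bias per unit
    of centred frequency.
    """
    t = np.asarray(t_stats, dtype=float)
    f = np.asarray(freqs, dtype=float)
    if t.shape != f.shape or t.ndim != 1:
        raise ValueError("t_stats and freqs must be matching 1-d arrays")
    if t.size < 10:
        raise ValueError("need >= 10 SNPs to fit the cf adjustment")
    cf = f - 0.5
    denom = float(cf @ cf)
    if denom == 0.0:
        warnings.warn("all centred frequencies are zero; cf adjustment is the identity")
        return AdjustmentFit(comparison_label, 0.0), t.copy()
    slope = float(cf @ t) / denom
    return AdjustmentFit(comparison_label, slope), t - slope * cf


def maf_genomic_control(
    chi2: np.ndarray,
    maf: np.ndarray,
    degree: int = 3,
) -> tuple[np.ndarray, AdjustmentFit]:
    """Step two: MAF-specific genomic control of chi-square statistics.

    Fits chi2 ~ 1 + MAF + ... + MAF^degree by least squares and divides each
    statistic by its fitted value, then rescales so the adjusted values
    average exactly 1 (plain division alone leaves the mean only
    approximately 1).  If any fitted value is non-positive the polynomial is
    abandoned for constant genomic control (division by the overall mean),
    with a warning.
    """
    c = np.asarray(chi2, dtype=float)
    m = np.asarray(maf, dtype=float)
    if c.shape != m.shape or c.ndim != 1:
        raise ValueError("chi2 and maf must be matching 1-d arrays")
    if c.size < 50:
        raise ValueError("need >= 50 SNPs for MAF-specific genomic control")
    if np.any((m <= 0) | (m > 0.5)):
        raise ValueError("maf values must lie in (0, 0.5]")
    X = np.vander(m, degree + 1, increasing=True)
    coeffs, *_ = np.linalg.lstsq(X, c, rcond=None)
    fitted = X @ coeffs
    if np.any(fitted <= 0.0):
        warnings.warn(
            "non-positive fitted chi-square values; falling back to constant genomic control"
        )
        coeffs = np.array([c.mean()] + [0.0] * degree)
        fitted = np.full_like(c, c.mean())
    adjusted = c / fitted
    rescale = adjusted.mean()
    adjusted = adjusted / rescale
    fit = AdjustmentFit(
        comparison_label="", slope_cf=math.nan, poly_coeffs=tuple(coeffs), gc_rescale=float(rescale)
    )
    return adjusted, fit


def two_step_adjust(
    t_stats: np.ndarray,
    freqs: np.ndarray,
    comparison_label: str = "",
) -> tuple[np.ndarray, AdjustmentFit]:
    """Full adjustment sequence: cf residuals, chi-square GC, final signed z.

    Order of operations: t-adjustment on cf, chi-square computed from the
    adjusted t, MAF-specific genomic control, and finally
    z = sign(adjusted t) * sqrt(adjusted chi2).
    """
    fit1, t_adj = fit_cf_adjustment(t_stats, freqs, comparison_label)
    f = np.asarray(freqs, dtype=float)
    maf = np.minimum(f, 1.0 - f)
    chi2_adj, fit2 = maf_genomic_control(t_adj**2, maf)
    z = np.sign(t_adj) * np.sqrt(chi2_adj)
    fit = AdjustmentFit(
        comparison_label=comparison_label,
        slope_cf=fit1.slope_cf,
        poly_coeffs=fit2.poly_coeffs,
        gc_rescale=fit2.gc_rescale,
    )
    return z, fit


def bias_diagnostics(
    scan: pd.DataFrame,
    comparisons: Sequence[str] = ("tntc", "wspc", "bspc"),
    maf_split: float = 0.25,
    discordance_p: float = 5e-8,
    min_bspc_p: float = 0.05,
) -> pd.DataFrame:
    """Per-comparison error diagnostics over a scan table.

    For each comparison reports the correlation of t with centred allele
    frequency (a major-allele bias indicator), the mean chi-square overall
    and within MAF strata (above/below ``maf_split``), and the number of
    SNPs that are genome-wide significant in this comparison while not even
    nominally significant with BSPC (data-artefact flags, the pattern seen
    in difficult extended-LD regions).
    """
    from scipy.stats import norm

    if len(scan) < 100:
        raise ValueError("need >= 100 SNPs for meaningful diagnostics")
    cf = scan["f_sample"].to_numpy() - 0.5
    maf = scan["maf"].to_numpy()
    bspc_p = 2.0 * norm.sf(np.abs(scan["bspc_t"].to_numpy()))
    rows = []
    for comp in comparisons:
        t = scan[f"{comp}_t"].to_numpy()
        ok = np.isfinite(t)
        chi2 = t[ok] ** 2
        p = 2.0 * norm.sf(np.abs(t))
        discordant = int(
            np.sum((p < discordance_p) & (bspc_p > min_bspc_p) & ok)
        ) if comp != "bspc" else 0
        rows.append(
            {
                "comparison": comp,
                "n_snps": int(ok.sum()),
                "cor_t_cf": float(np.corrcoef(t[ok], cf[ok])[0, 1]) if ok.sum() > 2 else math.nan,
                "mean_chi2": float(chi2.mean()),
                "mean_chi2_high_maf": float(chi2[maf[ok] > maf_split].mean())
                if np.any(maf[ok] > maf_split)
                else math.nan,
                "mean_chi2_low_maf": float(chi2[maf[ok] <= maf_split].mean())
                if np.any(maf[ok] <= maf_split)
                else math.nan,
                "n_discordant_vs_bspc": discordant,
            }
        )
    return pd.DataFrame(rows)
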