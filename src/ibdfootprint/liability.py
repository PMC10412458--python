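"""Closed-form liability-threshold mathematics for participation.

Participation in a study is modelled as a latent liability score X with a
(near) standard-normal distribution; an individual participates (I = 1)
exactly when X exceeds the threshold tau = Phi^-1(1 - alpha), where alpha is
the marginal participation rate.  Correlation of participation between
relatives arises through correlation of their liability scores.  This module
collects every quantity of the model that has a closed form or reduces to a
one-dimensional quadrature:

* the threshold tau and the liability--participation correlation cor(X, I);
* the sibling recurrence participation rate ratio lambda_S, a bivariate
  normal orthant probability, and its inverse (sibling liability correlation
  implied by an observed lambda_S);
* the selection shift of the genetic component among participants;
* the chain of adjustment factors that converts an observed-scale (0/1)
  heritability estimate into the heritability of the liability score, for
  study designs based on between-sib-pair (IBD2 vs IBD0) comparisons.

Observed-scale heritabilities are accepted as plain numbers, typically from
LD score regression run upstream; nothing here re-estimates them.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize
from scipy.stats import norm

__all__ = [
    "LiabilityModel",
    "HeritabilityChain",
    "bvn_upper_orthant",
    "threshold_from_rate",
    "cor_liability_participation",
    "sibling_recurrence_ratio",
    "liability_corr_for_lambda",
    "mean_genetic_shift",
    "liability_h2_from_observed",
    "bspc_efficiency_factor",
    "shrinkage_factor",
    "primary_h2_chain",
    "secondary_h2_chain",
    "direct_genetic_share",
]

_MODES = ("additive", "dominant", "recessive")


def _check_rate(alpha: float, name: str = "alpha") -> None:
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"{name} must lie strictly in (0, 1); got {alpha!r}")


def threshold_from_rate(alpha: float) -> float:
    """Participation threshold tau = Phi^-1(1 - alpha) on the liability scale.

    Parameters
    ----------
    alpha:
        Marginal participation rate, strictly in (0, 1).

    Returns
    -------
    float
        Standard-normal quantile such that P(X > tau) = alpha.
    """
    _check_rate(alpha)
    return float(norm.isf(alpha))


def cor_liability_participation(alpha: float) -> float:
    """Correlation between liability X and the 0/1 participation indicator I.

    For a standard-normal liability thresholded at tau = Phi^-1(1 - alpha),

        cor(X, I) = phi(tau) / sqrt(alpha (1 - alpha)),

    with phi the standard-normal density.  Symmetric in alpha <-> 1 - alpha.
    """
    _check_rate(alpha)
    tau = threshold_from_rate(alpha)
    return float(norm.pdf(tau) / math.sqrt(alpha * (1.0 - alpha)))


def bvn_upper_orthant(t1: float, t2: float, rho: float) -> float:
    """P(X1 > t1, X2 > t2) for standard bivariate normal with correlation rho.

    Computed by adaptive quadrature of the conditional tail probability,
    P = int_t1^inf phi(x) * Phi-bar((t2 - rho x) / sqrt(1 - rho^2)) dx,
    to absolute tolerance ~1e-12.
    """
    if rho == 0.0:
        return float(norm.sf(t1) * norm.sf(t2))
    if rho >= 1.0 - 1e-14:
        return float(norm.sf(max(t1, t2)))
    s = math.sqrt(1.0 - rho * rho)

    def integrand(x: float) -> float:
        return norm.pdf(x) * norm.sf((t2 - rho * x) / s)

    val, err = integrate.quad(integrand, t1, np.inf, epsabs=1e-13, epsrel=1e-11, limit=400)
    if err > 1e-8:
        raise RuntimeError(
            f"bivariate-normal orthant quadrature did not converge: "
            f"estimate {val:.6g}, error bound {err:.2g} (t1={t1}, t2={t2}, rho={rho})"
        )
    return float(val)


def _bvn_upper_orthant(tau: float, rho: float) -> float:
    return bvn_upper_orthant(tau, tau, rho)


def sibling_recurrence_ratio(alpha: float, sib_corr: float) -> float:
    """Sibling recurrence participation rate ratio lambda_S.

    lambda_S = P(X1 > tau and X2 > tau) / alpha^2 for sibling liabilities
    (X1, X2) bivariate standard normal with correlation ``sib_corr``.
    Equivalently, the participation rate of an individual given a
    participating sibling, divided by the marginal rate alpha.

    lambda_S = 1 at sib_corr = 0 and increases monotonically to 1/alpha as
    sib_corr -> 1.
    """
    _check_rate(alpha)
    if not (0.0 <= sib_corr < 1.0 + 1e-12):
        raise ValueError(f"sib_corr must lie in [0, 1); got {sib_corr!r}")
    tau = threshold_from_rate(alpha)
    p_both = _bvn_upper_orthant(tau, min(sib_corr, 1.0))
    return float(p_both / alpha**2)


def liability_corr_for_lambda(alpha: float, lambda_s: float, tol: float = 1e-10) -> float:
    """Sibling liability correlation implied by an observed lambda_S.

    Inverts :func:`sibling_recurrence_ratio` by root finding.  lambda_S must
    lie in the feasible range [1, 1/alpha].
    """
    _check_rate(alpha)
    if not (1.0 - 1e-9 <= lambda_s <= 1.0 / alpha + 1e-9):
        raise ValueError(
            f"lambda_s={lambda_s!r} outside feasible range [1, 1/alpha] = [1, {1.0 / alpha:.4g}]"
        )
    if abs(lambda_s - 1.0) <= 1e-12:
        return 0.0
    hi = 1.0 - 1e-12
    lam_hi = sibling_recurrence_ratio(alpha, hi)
    if lambda_s >= lam_hi:
        return hi

    def f(rho: float) -> float:
        return sibling_recurrence_ratio(alpha, rho) - lambda_s

    return float(optimize.brentq(f, 0.0, hi, xtol=tol))


def mean_genetic_shift(alpha: float, h2: float) -> float:
    """Mean of the genetic component among participants, in s.d. units of G.

    Under the liability-threshold model the liability of participants is a
    truncated normal with mean phi(tau)/alpha above the population mean; the
    genetic component G, with cor(G, X) = sqrt(h2), shifts by

        sqrt(h2) * phi(tau) / alpha

    standard deviations of G.
    """
    _check_rate(alpha)
    if not (0.0 <= h2 <= 1.0):
        raise ValueError(f"h2 must lie in [0, 1]; got {h2!r}")
    tau = threshold_from_rate(alpha)
    return float(math.sqrt(h2) * norm.pdf(tau) / alpha)


def liability_h2_from_observed(h2_obs: float, alpha: float) -> float:
    """Convert observed-scale (0/1 trait) heritability to liability scale.

    h2(X) = h2(I) / cor^2(X, I).  A result above 1 triggers a warning (noisy
    observed-scale estimates can produce this) but is returned as computed.
    """
    if h2_obs < 0:
        raise ValueError(f"h2_obs must be >= 0; got {h2_obs!r}")
    c = cor_liability_participation(alpha)
    out = h2_obs / c**2
    if out > 1.0:
        warnings.warn(
            f"liability-scale heritability {out:.3g} exceeds 1; inputs are inconsistent",
            stacklevel=2,
        )
    return float(out)


def bspc_efficiency_factor(case_frac_design: float, alpha: float) -> float:
    """Design-efficiency adjustment between a case/control split and alpha.

    The sampling variance of a two-group frequency comparison is proportional
    to 1/n_cases + 1/n_controls.  A design with case fraction c (e.g. the
    ~1:2 IBD2:IBD0 split of the between-sib-pair comparison) is more
    efficient than the alpha : (1 - alpha) participant split; the factor

        [1/c + 1/(1 - c)] / [1/alpha + 1/(1 - alpha)]

    rescales an observed-scale heritability accordingly.  Equals 1 when
    c = alpha.
    """
    _check_rate(case_frac_design, "case_frac_design")
    _check_rate(alpha)
    num = 1.0 / case_frac_design + 1.0 / (1.0 - case_frac_design)
    den = 1.0 / alpha + 1.0 / (1.0 - alpha)
    return float(num / den)


def shrinkage_factor(ratio_ibd: float, alpha: float) -> float:
    """Adjustment for the shrinkage of the IBD2-vs-IBD0 frequency difference.

    The expected frequency difference between IBD2 and IBD0 sib-pairs is
    smaller than the participant vs nonparticipant difference by the factor
    ratio_ibd * (1 - alpha), where ratio_ibd is the simulated expectation of
    (F_IBD2 - F_IBD0)/(F_samp - f_pop) (about 0.86 at lambda_S = 2).  Since
    efficiency scales with effect^2, the heritability adjustment is

        (1 / (ratio_ibd * (1 - alpha)))^2.
    """
    if ratio_ibd <= 0.0:
        raise ValueError(f"ratio_ibd must be > 0; got {ratio_ibd!r}")
    if ratio_ibd > 1.2:
        raise ValueError(f"ratio_ibd={ratio_ibd!r} fails sanity bound (<= 1.2)")
    if not (0.0 <= alpha < 1.0):
        raise ValueError(f"alpha must lie in [0, 1); got {alpha!r}")
    return float((1.0 / (ratio_ibd * (1.0 - alpha))) ** 2)


@dataclass(frozen=True)
class HeritabilityChain:
    """Observed-scale heritability and the adjustments to the liability scale.

    h2_liability = h2_observed * factor_liability * factor_efficiency
                 * factor_shrinkage, where the factors respectively account
    for (i) thresholding of the liability into a 0/1 indicator, (ii) the
    case/control balance of the comparison design relative to the
    participation split, and (iii) the shrinkage of the IBD-based frequency
    contrast relative to the participant/nonparticipant contrast.
    """

    h2_observed: float
    alpha: float
    factor_liability: float
    factor_efficiency: float
    factor_shrinkage: float

    @property
    def h2_liability(self) -> float:
        return (
            self.h2_observed
            * self.factor_liability
            * self.factor_efficiency
            * self.factor_shrinkage
        )

    def as_rows(self) -> list[tuple[str, float]]:
        return [
            ("h2_observed", self.h2_observed),
            ("alpha", self.alpha),
            ("factor_liability", self.factor_liability),
            ("factor_efficiency", self.factor_efficiency),
            ("factor_shrinkage", self.factor_shrinkage),
            ("h2_liability", self.h2_liability),
        ]


def primary_h2_chain(
    h2_obs: float,
    alpha: float,
    ratio_ibd: float = 0.86,
    case_frac_design: float = 1.0 / 3.0,
) -> HeritabilityChain:
    """Full adjustment chain from observed-scale h2 to liability-scale h2.

    All intermediates are kept at full precision.  For a secondary
    participation event measured directly on participants vs
    nonparticipants, pass ``ratio_ibd=1`` and ``case_frac_design=alpha``;
    the efficiency and shrinkage factors are then exactly 1 and the chain
    reduces to the liability conversion alone.
    """
    if h2_obs < 0:
        raise ValueError(f"h2_obs must be >= 0; got {h2_obs!r}")
    c = cor_liability_participation(alpha)
    chain = HeritabilityChain(
        h2_observed=h2_obs,
        alpha=alpha,
        factor_liability=1.0 / c**2,
        factor_efficiency=bspc_efficiency_factor(case_frac_design, alpha),
        factor_shrinkage=shrinkage_factor(ratio_ibd, alpha),
    )
    if chain.h2_liability > 1.0:
        warnings.warn(
            f"liability-scale heritability {chain.h2_liability:.3g} exceeds 1",
            stacklevel=2,
        )
    return chain


def secondary_h2_chain(h2_obs: float, alpha: float) -> HeritabilityChain:
    """Adjustment chain for a directly measured participation event.

    When the observed-scale GWAS already contrasts participants with
    nonparticipants at their natural alpha : (1 - alpha) split (secondary
    participation within a study), the design-efficiency and shrinkage
    factors are exactly 1 and only the liability conversion remains.
    """
    if h2_obs < 0:
        raise ValueError(f"h2_obs must be >= 0; got {h2_obs!r}")
    c = cor_liability_participation(alpha)
    return HeritabilityChain(
        h2_observed=h2_obs,
        alpha=alpha,
        factor_liability=1.0 / c**2,
        factor_efficiency=1.0,
        factor_shrinkage=1.0,
    )


def direct_genetic_share(h2: float, sib_corr: float) -> float:
    """Fraction of sibling liability correlation explained by direct genetics.

    Siblings share half their genomes, so a liability heritability h2
    contributes h2/2 to the correlation of their liability scores; the share
    of an observed correlation attributable to direct genetic effects is
    (h2/2)/sib_corr.
    """
    if sib_corr <= 0.0:
        raise ValueError(f"sib_corr must be > 0; got {sib_corr!r}")
    return float((h2 / 2.0) / sib_corr)


@dataclass(frozen=True)
class LiabilityModel:
    """Generative liability model for a family cohort.

    The liability of individual j in family i is

        X_ij = sum_k w1_k g_ijk + wA A_i + wB B_ij

    with g standardized genotype codes (mode-specific), A_i a family-shared
    standard-normal component and B_ij an individual component, all mutually
    independent, and weights satisfying sum w1_k^2 + wA^2 + wB^2 = 1 so that
    var(X) = 1.  Since cor(g_i1, g_i2) = 1/2 for siblings, the sibling
    liability correlation is wA^2 + (sum w1_k^2)/2.

    Parameters
    ----------
    alpha:
        Marginal participation rate.
    sib_corr:
        Target correlation of siblings' liability scores (genetic plus
        shared-environment), in [0, 1).
    mode:
        Genotype coding of causal SNPs: ``additive`` (standardized allele
        count), ``dominant`` (standardized indicator of >= 1 copy) or
        ``recessive`` (standardized indicator of 2 copies).
    """

    alpha: float
    sib_corr: float = 0.0
    mode: str = "additive"
    tau: float = field(init=False)

    def __post_init__(self) -> None:
        _check_rate(self.alpha)
        if not (0.0 <= self.sib_corr < 1.0):
            raise ValueError(f"sib_corr must lie in [0, 1); got {self.sib_corr!r}")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}; got {self.mode!r}")
        object.__setattr__(self, "tau", threshold_from_rate(self.alpha))

    def component_weights(self, total_var_share: float) -> tuple[float, float]:
        """(wA, wB) given the summed SNP variance share sum_k w1_k^2."""
        if not (0.0 <= total_var_share < 1.0):
            raise ValueError(f"total SNP variance share must lie in [0, 1); got {total_var_share!r}")
        wa2 = self.sib_corr - total_var_share / 2.0
        if wa2 < -1e-12:
            raise ValueError(
                "SNP variance shares alone exceed the target sibling correlation; "
                f"need sum(var_share)/2 <= sib_corr = {self.sib_corr}"
            )
        wa2 = max(wa2, 0.0)
        wb2 = 1.0 - total_var_share - wa2
        if wb2 < 0.0:
            raise ValueError("component variances exceed 1; reduce var shares or sib_corr")
        return math.sqrt(wa2), math.sqrt(wb2)

    @property
    def lambda_s(self) -> float:
        return sibling_recurrence_ratio(self.alpha, self.sib_corr)

    @classmethod
    def from_lambda(cls, alpha: float, lambda_s: float, mode: str = "additive") -> "LiabilityModel":
        """Build a model whose sibling correlation reproduces lambda_S."""
        return cls(alpha=alpha, sib_corr=liability_corr_for_lambda(alpha, lambda_s), mode=mode)
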