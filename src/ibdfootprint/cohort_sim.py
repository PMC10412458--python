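"""Forward simulation of family cohorts under liability-threshold ascertainment.

Families consist of two unrelated founders and two offspring produced by
Mendelian transmission with Haldane recombination between map positions.
Each family member receives a liability score

    X = sum_k w1_k g_k + wA A + wB B

(g: standardized genotype of causal SNP k; A: family-shared component;
B: individual component) and participates in the study when X exceeds the
threshold implied by the participation rate alpha.  The simulator tracks
grandparental origin of every transmitted allele, so the IBD state of every
sib pair at every SNP is known exactly, as is the identity of shared and
not-shared alleles.  A second, "called" genotype layer can be derived from
the truth layer by injecting genotyping errors (random genotype
replacement), phasing switch errors, and direct miscalls of the shared
allele at double-heterozygous sites.

Member layout within a family: index 0 = father, 1 = mother, 2 and 3 = the
two offspring.  Sib-pair cohorts pair members (2, 3); parent-offspring
cohorts pair (0, 2) and, when both parents participate, additionally (1, 2)
(the two transmissions are independent, so an ascertained couple with an
ascertained offspring contributes two pairs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from ibdfootprint.liability import LiabilityModel

__all__ = [
    "SnpSpec",
    "ErrorModel",
    "SibPairCohort",
    "FrequencySummary",
    "simulate_cohort",
    "frequency_summaries",
    "inject_errors",
    "estimate_lambda_s",
    "single_snp_summary",
    "standardized_genotype",
]

FATHER, MOTHER, OFF1, OFF2 = 0, 1, 2, 3


@dataclass(frozen=True)
class SnpSpec:
    """Specification of one simulated SNP.

    Parameters
    ----------
    f_pop:
        Population frequency of allele 1, strictly in (0, 1).
    var_share:
        Fraction of liability variance explained by this SNP (w1^2).
    mode:
        Effect coding: additive, dominant or recessive.
    map_position:
        Genetic map position in cM (used for Haldane recombination).
    chrom:
        Chromosome label; SNPs on different chromosomes assort independently.
    """

    f_pop: float
    var_share: float = 0.0
    mode: str = "additive"
    map_position: float = 0.0
    chrom: str = "1"

    def __post_init__(self) -> None:
        if not (0.0 < self.f_pop < 1.0):
            raise ValueError(f"f_pop must lie in (0, 1); got {self.f_pop!r}")
        if not (0.0 <= self.var_share < 1.0):
            raise ValueError(f"var_share must lie in [0, 1); got {self.var_share!r}")
        if self.mode not in ("additive", "dominant", "recessive"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class ErrorModel:
    """Error-injection configuration for the called genotype layer.

    genotype_error_rate:
        Per-individual, per-SNP probability that the genotype is replaced by
        a fresh Hardy-Weinberg draw from the population (phase randomized).
        This leaves the marginal distribution of called genotypes unchanged.
    phasing_switch_rate:
        Probability of a haplotype switch error between each pair of
        consecutive heterozygous sites of an individual.
    double_het_error_fn:
        Optional callable eps(f): at a double-heterozygous IBD1 site of a
        sib pair, the truly shared allele 1 is miscalled as 0 with
        probability eps(f) and a truly shared 0 miscalled as 1 with
        probability eps(1 - f), where f is the SNP's allele-1 frequency.
        Implemented by flipping the phase of the site in both siblings.
    """

    genotype_error_rate: float = 0.0
    phasing_switch_rate: float = 0.0
    double_het_error_fn: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        for name in ("genotype_error_rate", "phasing_switch_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]; got {v!r}")
            if v > 0.1:
                import warnings

                warnings.warn(f"{name}={v} is large; the error model targets small rates")


def standardized_genotype(g: np.ndarray, f: float, mode: str) -> np.ndarray:
    """Standardize allele-count genotypes (0/1/2) under the given effect coding."""
    if mode == "additive":
        mu = 2.0 * f
        sd = math.sqrt(2.0 * f * (1.0 - f))
        return (g - mu) / sd
    if mode == "dominant":
        p = 1.0 - (1.0 - f) ** 2
    elif mode == "recessive":
        p = f * f
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ind = (g >= 1) if mode == "dominant" else (g == 2)
    return (ind.astype(np.float64) - p) / math.sqrt(p * (1.0 - p))


@dataclass
class SibPairCohort:
    """A simulated cohort of nuclear families with full transmission truth.

    Arrays are indexed (family, member, haplotype, snp) for haplotypes and
    (family, offspring, snp) for transmission origins; see module docstring
    for the member layout.
    """

    pair_type: str
    snps: list[SnpSpec]
    model: LiabilityModel
    haplotypes: np.ndarray  # (n, 4, 2, L) uint8, truth layer
    pat_origin: np.ndarray  # (n, 2, L) uint8; which father haplotype each offspring got
    mat_origin: np.ndarray  # (n, 2, L) uint8
    ibd_state: np.ndarray  # (n, L) uint8, sib pair IBD truth
    liability: np.ndarray  # (n, 4) float64
    participates: np.ndarray  # (n, 4) bool
    called_haplotypes: np.ndarray | None = None  # error-bearing layer

    @property
    def n_pairs(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[3]

    def genotypes(self, layer: str = "truth") -> np.ndarray:
        """Allele-count genotypes, shape (n, 4, L)."""
        return self._haps(layer).sum(axis=2)

    def _haps(self, layer: str) -> np.ndarray:
        if layer == "truth":
            return self.haplotypes
        if layer == "called":
            if self.called_haplotypes is None:
                raise ValueError("no called layer present; run inject_errors first")
            return self.called_haplotypes
        raise ValueError(f"unknown layer {layer!r}")

    def shared_parent(self) -> np.ndarray:
        """Per-pair per-SNP origin pattern of IBD1 sharing.

        Returns an int8 array (n, L): 1 where the paternal transmission
        matches (shared allele is paternal), 2 where the maternal matches,
        0 elsewhere (IBD0 or IBD2).
        """
        pat = self.pat_origin[:, 0, :] == self.pat_origin[:, 1, :]
        mat = self.mat_origin[:, 0, :] == self.mat_origin[:, 1, :]
        out = np.zeros(pat.shape, dtype=np.int8)
        out[pat & ~mat] = 1
        out[mat & ~pat] = 2
        return out

    def truth_shared_allele(self) -> np.ndarray:
        """Truth shared-allele value at IBD1 sites (n, L); -1 elsewhere."""
        sp = self.shared_parent()
        pat_allele = self.haplotypes[:, OFF1, 0, :]
        mat_allele = self.haplotypes[:, OFF1, 1, :]
        out = np.full(sp.shape, -1, dtype=np.int8)
        out[sp == 1] = pat_allele[sp == 1]
        out[sp == 2] = mat_allele[sp == 2]
        return out


def _recomb_probs(snps: Sequence[SnpSpec]) -> np.ndarray:
    """Per-SNP probability that grandparental origin switches before the SNP.

    The first SNP (and the first SNP of every chromosome) starts a fresh
    meiosis: origin is uniform, encoded as switch probability 1/2.  Within a
    chromosome the Haldane map function gives r = (1 - exp(-2 d)) / 2 for
    map distance d in Morgans.
    """
    L = len(snps)
    p = np.empty(L)
    p[0] = 0.5
    for l in range(1, L):
        if snps[l].chrom != snps[l - 1].chrom:
            p[l] = 0.5
        else:
            d_morgan = (snps[l].map_position - snps[l - 1].map_position) / 100.0
            if d_morgan < 0:
                raise ValueError("map_position must be nondecreasing within a chromosome")
            p[l] = 0.5 * (1.0 - math.exp(-2.0 * d_morgan))
    return p


def _meiosis(rng: np.random.Generator, n: int, switch_p: np.ndarray) -> np.ndarray:
    """Grandparental origins (n, L) of one gamete as a Markov chain of switches."""
    sw = rng.random((n, switch_p.size)) < switch_p
    return np.bitwise_and(np.cumsum(sw, axis=1, dtype=np.int64), 1).astype(np.uint8)


def simulate_cohort(
    model: LiabilityModel,
    snps: Sequence[SnpSpec],
    n_pairs: int,
    pair_type: str = "sib",
    seed: int | np.random.SeedSequence | None = None,
) -> SibPairCohort:
    """Simulate a cohort of families with tracked IBD truth.

    Founder haplotypes are drawn in Hardy-Weinberg equilibrium at each SNP's
    population frequency; offspring are produced by Mendelian transmission
    with Haldane recombination between map positions; liabilities follow the
    family liability model and participation is thresholded at tau.

    Separate child random streams are used for founder draws, meioses and
    environmental components, so error injection (which uses its own stream)
    is reproducible independently of the cohort draw.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if pair_type not in ("sib", "parent_offspring"):
        raise ValueError(f"unknown pair_type {pair_type!r}")
    snps = list(snps)
    if not snps:
        raise ValueError("at least one SnpSpec is required")
    total_share = sum(s.var_share for s in snps)
    if total_share >= 1.0:
        raise ValueError("summed var_share across SNPs must be < 1")
    wa, wb = model.component_weights(total_share)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_founder, rng_meiosis, rng_env = (np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(3))

    n, L = int(n_pairs), len(snps)
    freqs = np.array([s.f_pop for s in snps])
    haplotypes = np.empty((n, 4, 2, L), dtype=np.uint8)
    haplotypes[:, :2] = rng_founder.random((n, 2, 2, L)) < freqs

    switch_p = _recomb_probs(snps)
    pat_origin = np.empty((n, 2, L), dtype=np.uint8)
    mat_origin = np.empty((n, 2, L), dtype=np.uint8)
    for j in range(2):
        pat_origin[:, j] = _meiosis(rng_meiosis, n, switch_p)
        mat_origin[:, j] = _meiosis(rng_meiosis, n, switch_p)
        father, mother = haplotypes[:, FATHER], haplotypes[:, MOTHER]
        haplotypes[:, OFF1 + j, 0] = np.take_along_axis(father, pat_origin[:, j][:, None, :], axis=1)[:, 0]
        haplotypes[:, OFF1 + j, 1] = np.take_along_axis(mother, mat_origin[:, j][:, None, :], axis=1)[:, 0]

    ibd_state = (
        (pat_origin[:, 0] == pat_origin[:, 1]).astype(np.uint8)
        + (mat_origin[:, 0] == mat_origin[:, 1]).astype(np.uint8)
    )

    geno = haplotypes.sum(axis=2, dtype=np.int64)
    genetic = np.zeros((n, 4))
    for l, snp in enumerate(snps):
        if snp.var_share > 0:
            genetic += math.sqrt(snp.var_share) * standardized_genotype(geno[:, :, l], snp.f_pop, snp.mode)

    a = rng_env.standard_normal(n)
    b = rng_env.standard_normal((n, 4))
    liability = genetic + wa * a[:, None] + wb * b
    participates = liability > model.tau

    return SibPairCohort(
        pair_type=pair_type,
        snps=snps,
        model=model,
        haplotypes=haplotypes,
        pat_origin=pat_origin,
        mat_origin=mat_origin,
        ibd_state=ibd_state,
        liability=liability,
        participates=participates,
    )


@dataclass(frozen=True)
class FrequencySummary:
    """Allele-1 frequencies of one SNP in the strata used by the method.

    Sib-pair strata are defined over the offspring population (the cohort of
    potential participants); parents are generative machinery only.  For
    parent-offspring cohorts the population is both parents plus the first
    offspring, and the transmitted/nontransmitted frequencies are tallied
    over ascertained parent-offspring pairs.  Empty strata yield NaN.
    """

    f_pop: float
    f_samp: float
    f_nonparticipants: float
    alpha_realized: float
    f_ibd2: float = math.nan
    f_ibd0: float = math.nan
    f_ibd1s: float = math.nan
    f_ibd1ns: float = math.nan
    f_sibs: float = math.nan
    f_sing: float = math.nan
    f_t: float = math.nan
    f_nt: float = math.nan
    n_both: int = 0
    n_ibd2: int = 0
    n_ibd0: int = 0
    n_ibd1: int = 0
    n_sing: int = 0
    n_po_pairs: int = 0

    @property
    def eq_identity_residual(self) -> float:
        """Residual of the exact identity linking sample and population frequencies.

        (F_samp - f_pop) = (1 - alpha)(F_samp - F_nonparticipants) holds as
        an algebraic identity on realized counts; the residual is zero up to
        float rounding.
        """
        return (self.f_samp - self.f_pop) - (1.0 - self.alpha_realized) * (
            self.f_samp - self.f_nonparticipants
        )

    @property
    def ratio_bspc(self) -> float:
        return (self.f_ibd2 - self.f_ibd0) / (self.f_samp - self.f_pop)

    @property
    def ratio_wspc(self) -> float:
        return (self.f_ibd1s - self.f_ibd1ns) / (self.f_samp - self.f_pop)

    @property
    def ratio_sibs(self) -> float:
        return (self.f_sibs - self.f_sing) / (self.f_samp - self.f_pop)


def _safe_freq(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def frequency_summaries(cohort: SibPairCohort, snp_index: int) -> FrequencySummary:
    """Tally the stratified allele frequencies of one SNP from simulation truth."""
    l = snp_index
    haps = cohort.haplotypes
    if cohort.pair_type == "sib":
        g = haps[:, OFF1:, :, l].sum(axis=2, dtype=np.int64)  # (n, 2)
        part = cohort.participates[:, OFF1:]
        f_pop = g.sum() / (4.0 * cohort.n_pairs)
        n_part = int(part.sum())
        f_samp = _safe_freq(float(g[part].sum()), 2.0 * n_part)
        f_non = _safe_freq(float(g[~part].sum()), 2.0 * (2 * cohort.n_pairs - n_part))
        alpha_real = n_part / (2.0 * cohort.n_pairs)

        both = part[:, 0] & part[:, 1]
        state = cohort.ibd_state[:, l]
        m2, m0, m1 = both & (state == 2), both & (state == 0), both & (state == 1)
        # IBD2: the pair carries 2 distinct-by-descent alleles = either sib's genotype
        f_ibd2 = _safe_freq(float(g[m2, 0].sum()), 2.0 * m2.sum())
        f_ibd0 = _safe_freq(float(g[m0].sum()), 4.0 * m0.sum())

        sp = cohort.shared_parent()[:, l]
        pat1, mat1 = haps[:, OFF1, 0, l], haps[:, OFF1, 1, l]
        pat2, mat2 = haps[:, OFF2, 0, l], haps[:, OFF2, 1, l]
        shared = np.where(sp == 1, pat1, mat1)
        ns_sum = np.where(sp == 1, mat1 + mat2, pat1 + pat2)
        f_ibd1s = _safe_freq(float(shared[m1].sum()), float(m1.sum()))
        f_ibd1ns = _safe_freq(float(ns_sum[m1].sum()), 2.0 * m1.sum())

        sing1 = part[:, 0] & ~part[:, 1]
        sing2 = part[:, 1] & ~part[:, 0]
        n_sing = int(sing1.sum() + sing2.sum())
        f_sibs = _safe_freq(float(g[both].sum()), 4.0 * both.sum())
        f_sing = _safe_freq(float(g[sing1, 0].sum() + g[sing2, 1].sum()), 2.0 * n_sing)
        return FrequencySummary(
            f_pop=float(f_pop),
            f_samp=f_samp,
            f_nonparticipants=f_non,
            alpha_realized=alpha_real,
            f_ibd2=f_ibd2,
            f_ibd0=f_ibd0,
            f_ibd1s=f_ibd1s,
            f_ibd1ns=f_ibd1ns,
            f_sibs=f_sibs,
            f_sing=f_sing,
            n_both=int(both.sum()),
            n_ibd2=int(m2.sum()),
            n_ibd0=int(m0.sum()),
            n_ibd1=int(m1.sum()),
            n_sing=n_sing,
        )

    # parent-offspring: population = father, mother, first offspring
    members = [FATHER, MOTHER, OFF1]
    g = haps[:, :, :, l][:, members].sum(axis=2, dtype=np.int64)
    part = cohort.participates[:, members]
    f_pop = g.sum() / (2.0 * g.size)
    n_part = int(part.sum())
    f_samp = _safe_freq(float(g[part].sum()), 2.0 * n_part)
    f_non = _safe_freq(float(g[~part].sum()), 2.0 * (g.size - n_part))
    alpha_real = n_part / float(g.size)

    t_vals, nt_vals = [], []
    off_part = cohort.participates[:, OFF1]
    for parent, origin, off_hap in (
        (FATHER, cohort.pat_origin[:, 0, l], haps[:, OFF1, 0, l]),
        (MOTHER, cohort.mat_origin[:, 0, l], haps[:, OFF1, 1, l]),
    ):
        mask = cohort.participates[:, parent] & off_part
        nt = np.take_along_axis(haps[:, parent, :, l], (1 - origin)[:, None].astype(np.int64), axis=1)[:, 0]
        t_vals.append(off_hap[mask])
        nt_vals.append(nt[mask])
    t_all = np.concatenate(t_vals)
    nt_all = np.concatenate(nt_vals)
    return FrequencySummary(
        f_pop=float(f_pop),
        f_samp=f_samp,
        f_nonparticipants=f_non,
        alpha_realized=alpha_real,
        f_t=_safe_freq(float(t_all.sum()), float(t_all.size)),
        f_nt=_safe_freq(float(nt_all.sum()), float(nt_all.size)),
        n_po_pairs=int(t_all.size),
    )


def estimate_lambda_s(cohort: SibPairCohort) -> float:
    """Sibling recurrence participation rate ratio from a simulated cohort.

    P(both siblings participate) / alpha_realized^2; NaN if no participating
    individuals.
    """
    if cohort.pair_type != "sib":
        raise ValueError("lambda_S is defined for sib cohorts")
    part = cohort.participates[:, OFF1:]
    alpha_real = part.mean()
    if alpha_real == 0:
        return math.nan
    p_both = (part[:, 0] & part[:, 1]).mean()
    return float(p_both / alpha_real**2)


def inject_errors(
    cohort: SibPairCohort,
    error_model: ErrorModel,
    seed: int | np.random.SeedSequence | None = None,
) -> SibPairCohort:
    """Derive an error-bearing called layer from the truth haplotypes.

    The truth layer is left untouched; a copy receives, in order, random
    genotype replacement, phasing switch errors, and (for sib cohorts with a
    configured eps function) direct double-heterozygote shared-allele
    miscalls.  Returns a new cohort object sharing the truth arrays.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng_geno, rng_phase, rng_dh = (np.random.Generator(np.random.PCG64(c)) for c in ss.spawn(3))

    called = cohort.haplotypes.copy()
    n, _, _, L = called.shape
    freqs = np.array([s.f_pop for s in cohort.snps])

    if error_model.genotype_error_rate > 0:
        mask = rng_geno.random((n, 4, L)) < error_model.genotype_error_rate
        draws = (rng_geno.random((n, 4, 2, L)) < freqs).astype(np.uint8)
        called = np.where(mask[:, :, None, :], draws, called)

    if error_model.phasing_switch_rate > 0:
        geno = called.sum(axis=2, dtype=np.int64)  # (n, 4, L)
        het = geno == 1
        # a switch may occur before every heterozygous site except the first
        eligible = het & (np.cumsum(het, axis=2) > 1)
        inc = eligible & (rng_phase.random((n, 4, L)) < error_model.phasing_switch_rate)
        orient = np.bitwise_and(np.cumsum(inc, axis=2, dtype=np.int64), 1).astype(bool)
        flipped = called[:, :, ::-1, :]
        called = np.where(orient[:, :, None, :], flipped, called)

    if error_model.double_het_error_fn is not None:
        eps = error_model.double_het_error_fn
        geno = called.sum(axis=2, dtype=np.int64)
        if cohort.pair_type == "sib":
            dh = (geno[:, OFF1] == 1) & (geno[:, OFF2] == 1) & (cohort.ibd_state == 1)
            truth_shared = cohort.truth_shared_allele()
            members = (OFF1, OFF2)
        else:
            # parent-offspring: the transmitted (paternal) allele is "shared"
            dh = (geno[:, FATHER] == 1) & (geno[:, OFF1] == 1)
            truth_shared = cohort.haplotypes[:, OFF1, 0, :].astype(np.int8)
            members = (FATHER, OFF1)
        p_flip = np.zeros((n, L))
        for l, f in enumerate(freqs):
            p_flip[:, l] = np.where(truth_shared[:, l] == 1, eps(f), eps(1.0 - f))
        flip = dh & (rng_dh.random((n, L)) < p_flip)
        for m in members:
            sub = called[:, m]  # (n, 2, L) view
            sel = np.broadcast_to(flip[:, None, :], sub.shape)
            swapped = sub[:, ::-1, :]
            called[:, m] = np.where(sel, swapped, sub)

    out = replace(cohort)
    out.called_haplotypes = called
    return out


# ---------------------------------------------------------------------------
# fast single-SNP replicate path (used by the ratio experiments)
# ---------------------------------------------------------------------------


def _participation_category_probs(model: LiabilityModel, snp: SnpSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Conditional participation probabilities for a sib pair given genotypes.

    Given the sib genotype pair (g1, g2), the liabilities are bivariate
    normal with means w1*gs(g_j), common variance 1 - w1^2 and correlation
    wA^2/(1 - w1^2); the joint participation outcome is therefore exactly a
    four-category draw.  Returns (p_both, p_only1, p_only2), each indexed by
    combo = 3*g1 + g2.
    """
    from ibdfootprint.liability import bvn_upper_orthant

    wa, _wb = model.component_weights(snp.var_share)
    w1 = math.sqrt(snp.var_share)
    gs = standardized_genotype(np.arange(3, dtype=np.float64), snp.f_pop, snp.mode)
    s2 = 1.0 - w1 * w1
    s = math.sqrt(s2)
    rho = (wa * wa) / s2
    thr = (model.tau - w1 * gs) / s  # per-genotype threshold for the residual
    from scipy.stats import norm as _norm

    p_both = np.empty(9)
    p_only1 = np.empty(9)
    p_only2 = np.empty(9)
    for g1 in range(3):
        for g2 in range(3):
            k = 3 * g1 + g2
            pb = bvn_upper_orthant(thr[g1], thr[g2], rho)
            p_both[k] = pb
            p_only1[k] = _norm.sf(thr[g1]) - pb
            p_only2[k] = _norm.sf(thr[g2]) - pb
    return p_both, p_only1, p_only2


# code layout for the 256-state tally: bits 0-3 = pat1, mat1, pat2, mat2
# (transmitted allele values), bit 4 = paternal origins match, bit 5 =
# maternal origins match, bits 6-7 = participation category
# (0 none, 1 only sib1, 2 only sib2, 3 both).
def _tally_vectors() -> dict[str, np.ndarray]:
    c = np.arange(256)
    pat1, mat1 = (c >> 0) & 1, (c >> 1) & 1
    pat2, mat2 = (c >> 2) & 1, (c >> 3) & 1
    patm, matm = ((c >> 4) & 1).astype(bool), ((c >> 5) & 1).astype(bool)
    cat = (c >> 6) & 3
    g1, g2 = pat1 + mat1, pat2 + mat2
    p1, p2 = cat % 2 == 1, cat >= 2  # participation of sib1 / sib2
    both = p1 & p2
    state2, state0, state1 = patm & matm, ~patm & ~matm, patm ^ matm
    shared = np.where(patm, pat1, mat1)
    ns_sum = np.where(patm, mat1 + mat2, pat1 + pat2)
    sing1, sing2 = p1 & ~p2, p2 & ~p1
    v = {
        "pop_num": g1 + g2,
        "pop_den": np.full(256, 4.0),
        "samp_num": g1 * p1 + g2 * p2,
        "samp_den": 2.0 * (p1.astype(float) + p2),
        "non_num": g1 * ~p1 + g2 * ~p2,
        "non_den": 2.0 * ((~p1).astype(float) + ~p2),
        "ibd2_num": g1 * (both & state2),
        "ibd2_den": 2.0 * (both & state2),
        "ibd0_num": (g1 + g2) * (both & state0),
        "ibd0_den": 4.0 * (both & state0),
        "s_num": shared * (both & state1),
        "s_den": 1.0 * (both & state1),
        "ns_num": ns_sum * (both & state1),
        "ns_den": 2.0 * (both & state1),
        "sibs_num": (g1 + g2) * both,
        "sibs_den": 4.0 * both,
        "sing_num": g1 * sing1 + g2 * sing2,
        "sing_den": 2.0 * (sing1.astype(float) + sing2),
        "n_both": 1.0 * both,
        "n_ibd2": 1.0 * (both & state2),
        "n_ibd0": 1.0 * (both & state0),
        "n_ibd1": 1.0 * (both & state1),
        "n_sing": 1.0 * (sing1 | sing2),
    }
    return {k: np.asarray(a, dtype=np.float64) for k, a in v.items()}


_TALLY_VECTORS = _tally_vectors()


def single_snp_summary(
    model: LiabilityModel,
    snp: SnpSpec,
    n_pairs: int,
    rng: np.random.Generator,
    chunk: int = 1 << 22,
) -> FrequencySummary:
    """One sib-pair replicate at a single unlinked SNP, in streaming chunks.

    Statistically equivalent to ``frequency_summaries(simulate_cohort(...), 0)``
    for a one-SNP sib cohort, but without materializing haplotype or
    liability arrays: founder alleles and transmissions are drawn as in the
    full simulator, while the joint participation outcome of the pair is
    drawn exactly from its conditional four-category distribution given the
    genotypes (the Gaussian components are integrated out analytically).
    Replicates of millions of pairs are then cheap.
    """
    f, mode = snp.f_pop, snp.mode
    p_both, p_only1, p_only2 = _participation_category_probs(model, snp)

    keys = [
        "pop_num", "pop_den", "samp_num", "samp_den", "non_num", "non_den",
        "ibd2_num", "ibd2_den", "ibd0_num", "ibd0_den",
        "s_num", "s_den", "ns_num", "ns_den",
        "sibs_num", "sibs_den", "sing_num", "sing_den",
        "n_both", "n_ibd2", "n_ibd0", "n_ibd1", "n_sing",
    ]
    acc = dict.fromkeys(keys, 0.0)

    counts = np.zeros(256, dtype=np.int64)
    remaining = int(n_pairs)
    while remaining > 0:
        m = min(chunk, remaining)
        remaining -= m
        fa0 = (rng.random(m) < f).astype(np.uint8)
        fa1 = (rng.random(m) < f).astype(np.uint8)
        mo0 = (rng.random(m) < f).astype(np.uint8)
        mo1 = (rng.random(m) < f).astype(np.uint8)
        tbits = rng.integers(0, 16, size=m, dtype=np.uint8)
        tp1, tp2 = tbits & 1, (tbits >> 1) & 1
        tm1, tm2 = (tbits >> 2) & 1, (tbits >> 3) & 1
        pat1 = np.where(tp1.astype(bool), fa1, fa0)
        pat2 = np.where(tp2.astype(bool), fa1, fa0)
        mat1 = np.where(tm1.astype(bool), mo1, mo0)
        mat2 = np.where(tm2.astype(bool), mo1, mo0)

        combo = (3 * (pat1 + mat1) + (pat2 + mat2)).astype(np.intp)
        u = rng.random(m)
        pb = p_both[combo]
        cat = (u < pb).astype(np.uint8)  # 1 if both (temporarily)
        cat = np.where(cat == 1, np.uint8(3), 0).astype(np.uint8)
        rest = cat == 0
        p1b = pb + p_only1[combo]
        cat = np.where(rest & (u < p1b), np.uint8(1), cat)
        rest = cat == 0
        cat = np.where(rest & (u < p1b + p_only2[combo]), np.uint8(2), cat)

        code = (
            pat1
            | (mat1 << 1)
            | (pat2 << 2)
            | (mat2 << 3)
            | ((tp1 == tp2).astype(np.uint8) << 4)
            | ((tm1 == tm2).astype(np.uint8) << 5)
            | (cat << 6)
        )
        counts += np.bincount(code, minlength=256)

    for k in keys:
        acc[k] = float(counts @ _TALLY_VECTORS[k])

    return FrequencySummary(
        f_pop=_safe_freq(acc["pop_num"], acc["pop_den"]),
        f_samp=_safe_freq(acc["samp_num"], acc["samp_den"]),
        f_nonparticipants=_safe_freq(acc["non_num"], acc["non_den"]),
        alpha_realized=acc["samp_den"] / acc["pop_den"],
        f_ibd2=_safe_freq(acc["ibd2_num"], acc["ibd2_den"]),
        f_ibd0=_safe_freq(acc["ibd0_num"], acc["ibd0_den"]),
        f_ibd1s=_safe_freq(acc["s_num"], acc["s_den"]),
        f_ibd1ns=_safe_freq(acc["ns_num"], acc["ns_den"]),
        f_sibs=_safe_freq(acc["sibs_num"], acc["sibs_den"]),
        f_sing=_safe_freq(acc["sing_num"], acc["sing_den"]),
        n_both=int(acc["n_both"]),
        n_ibd2=int(acc["n_ibd2"]),
        n_ibd0=int(acc["n_ibd0"]),
        n_ibd1=int(acc["n_ibd1"]),
        n_sing=int(acc["n_sing"]),
    )
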