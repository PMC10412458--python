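"""Per-SNP participation-association statistics and the genome scan.

Three comparisons test whether an allele is enriched in genetic material
shared by two participants relative to material carried by only one:

* TNTC - transmitted vs nontransmitted parental alleles in ascertained
  parent-offspring pairs (frequency difference F_T - F_NT);
* WSPC - shared vs not-shared alleles within sib pairs at IBD1 loci
  (F_IBD1S - F_IBD1NS);
* BSPC - allele frequency in IBD2 vs IBD0 sib pairs (F_IBD2 - F_IBD0).

TNTC and WSPC are one-sample t-tests of per-pair differences (the pairs'
differences are treated as independent); BSPC is a Welch two-sample t-test
of per-pair allele frequencies, with no HWE or within-pair independence
assumption.  A positive statistic always means allele 1 is enriched in the
shared / doubly-participating stratum.  Per-SNP statistics can be combined
across comparisons by a Stouffer combination weighted by the square root of
the effective number of pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ibdfootprint.ibd import (
    RESOLUTION_DIRECT,
    RESOLUTION_NEIGHBOR,
    AlleleClassification,
    IbdSegment,
    classify_pair_segment,
    trim_segments,
)

__all__ = [
    "ComparisonBlock",
    "GENOME_WIDE_SIGNIFICANCE",
    "one_sample_block",
    "two_sample_block",
    "tntc",
    "wspc",
    "bspc",
    "combine",
    "genome_scan",
]

GENOME_WIDE_SIGNIFICANCE = 5e-8

_RESOLVED = (RESOLUTION_DIRECT, RESOLUTION_NEIGHBOR)


@dataclass(frozen=True)
class ComparisonBlock:
    """One comparison's frequency difference, standard error and t-statistic.

    ``n_eff`` is the effective pair count used for combination weights; it
    equals ``n_pairs`` for the one-sample comparisons and the harmonic-mean
    count n2*n0/(n2+n0) for the two-sample comparison.
    """

    freq_diff: float = math.nan
    se: float = math.nan
    t: float = math.nan
    n_pairs: int = 0
    n_eff: float = math.nan

    @property
    def defined(self) -> bool:
        return math.isfinite(self.t)

    @property
    def chi2(self) -> float:
        return self.t**2


def one_sample_block(diffs: np.ndarray) -> ComparisonBlock:
    """One-sample construction: mean of per-pair differences over s.e. of the mean."""
    d = np.asarray(diffs, dtype=np.float64)
    d = d[np.isfinite(d)]
    n = d.size
    if n < 2:
        return ComparisonBlock(n_pairs=n)
    fd = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        # all differences identical: s.e. degenerate, statistic undefined
        return ComparisonBlock(freq_diff=fd, se=0.0, t=math.nan, n_pairs=n, n_eff=float(n))
    se = sd / math.sqrt(n)
    return ComparisonBlock(freq_diff=fd, se=se, t=fd / se, n_pairs=n, n_eff=float(n))


def two_sample_block(freqs_a: np.ndarray, freqs_b: np.ndarray) -> ComparisonBlock:
    """Welch two-sample construction on per-pair frequencies (a minus b)."""
    a = np.asarray(freqs_a, dtype=np.float64)
    b = np.asarray(freqs_b, dtype=np.float64)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        return ComparisonBlock(n_pairs=na + nb)
    fd = float(a.mean() - b.mean())
    var = a.var(ddof=1) / na + b.var(ddof=1) / nb
    n_eff = na * nb / (na + nb)
    if var == 0.0:
        t = math.nan if fd != 0.0 else 0.0
        return ComparisonBlock(freq_diff=fd, se=0.0, t=t, n_pairs=na + nb, n_eff=n_eff)
    se = math.sqrt(var)
    return ComparisonBlock(freq_diff=fd, se=se, t=fd / se, n_pairs=na + nb, n_eff=n_eff)


def _resolved_diffs(classifications: Iterable[AlleleClassification]) -> np.ndarray:
    out = []
    for c in classifications:
        if c.resolution in _RESOLVED and c.shared is not None and c.not_shared:
            out.append(c.shared - float(np.mean(c.not_shared)))
    return np.asarray(out)


def tntc(classifications: Iterable[AlleleClassification]) -> ComparisonBlock:
    """Transmitted-nontransmitted comparison at one SNP.

    Accepts parent-offspring classifications; each resolved pair contributes
    d = T - NT, and F_T - F_NT equals the mean of the per-pair differences.
    """
    return one_sample_block(_resolved_diffs(classifications))


def wspc(classifications: Iterable[AlleleClassification]) -> ComparisonBlock:
    """Within-sib-pair comparison at one SNP.

    Each resolved IBD1 pair contributes d = S - (NS1 + NS2)/2, so the mean
    of d equals F_IBD1S - F_IBD1NS.
    """
    return one_sample_block(_resolved_diffs(classifications))


def bspc(
    ibd2: Iterable[AlleleClassification | float],
    ibd0: Iterable[AlleleClassification | float],
) -> ComparisonBlock:
    """Between-sib-pairs comparison at one SNP.

    Accepts per-pair allele frequencies (floats) or classifications whose
    ``not_shared`` holds the pair's distinct alleles (2 for IBD2, 4 for
    IBD0).
    """

    def freqs(items: Iterable[AlleleClassification | float]) -> np.ndarray:
        vals = []
        for it in items:
            if isinstance(it, AlleleClassification):
                if it.resolution in _RESOLVED and it.not_shared:
                    vals.append(float(np.mean(it.not_shared)))
            else:
                vals.append(float(it))
        return np.asarray(vals)

    return two_sample_block(freqs(ibd2), freqs(ibd0))


def combine(blocks: Mapping[str, ComparisonBlock]) -> float:
    """Stouffer combination of the defined comparison statistics at one SNP.

    z_combined = sum_k sqrt(n_eff_k) z_k / sqrt(sum_k n_eff_k), which has
    unit variance under the null for independent blocks; with a single
    defined block it reduces to that block's statistic.
    """
    zs, ws = [], []
    for block in blocks.values():
        if block.defined and block.n_eff > 0:
            zs.append(block.t)
            ws.append(math.sqrt(block.n_eff))
    if not zs:
        return math.nan
    zs_arr, ws_arr = np.asarray(zs), np.asarray(ws)
    return float((ws_arr * zs_arr).sum() / math.sqrt((ws_arr**2).sum()))


def _default_po_segments(pair_id: str, chroms: Sequence[str]) -> list[IbdSegment]:
    """Whole-chromosome IBD1 segments for a parent-offspring pair."""
    segs = []
    chrom_arr = np.asarray(chroms, dtype=object)
    start = 0
    for l in range(1, len(chrom_arr) + 1):
        if l == len(chrom_arr) or chrom_arr[l] != chrom_arr[start]:
            segs.append(IbdSegment(pair_id, str(chrom_arr[start]), start, l, 1))
            start = l
    return segs


def genome_scan(
    bundle,
    maf_min: float = 0.01,
    exclusion_mask: Sequence[tuple[str, int, int]] | None = None,
    trim: int = 0,
) -> pd.DataFrame:
    """Scan every retained SNP for association with participation.

    Parameters
    ----------
    bundle:
        An :class:`ibdfootprint.io.DatasetBundle` (phased haplotypes, pair
        list and IBD segments; every individual present is a participant).
    maf_min:
        Minor-allele-frequency threshold; SNPs with sample MAF below it are
        dropped.
    exclusion_mask:
        (chrom, start, end) position intervals (0-based half-open) whose
        SNPs are excluded, e.g. the MHC and other extended-LD regions.
    trim:
        SNPs trimmed from both ends of every sib IBD segment before
        tallying (use ~250 for inferred segments; simulation-truth segments
        need no trimming).

    Returns
    -------
    pandas.DataFrame
        One row per retained SNP: variant columns, ``maf``, ``f_sample``,
        per-comparison ``{tntc,wspc,bspc}_{freq_diff,se,t,n}``,
        ``combined_z`` and its two-sided ``p``.
    """
    from scipy.stats import norm

    variants = bundle.variants
    L = len(variants)
    chroms = variants["chrom"].to_numpy()

    tntc_d: list[list[float]] = [[] for _ in range(L)]
    wspc_d: list[list[float]] = [[] for _ in range(L)]
    bspc2: list[list[float]] = [[] for _ in range(L)]
    bspc0: list[list[float]] = [[] for _ in range(L)]

    for pair in bundle.pairs.itertuples():
        h1 = bundle.haplotypes[bundle.sample_index[pair.id1]]
        h2 = bundle.haplotypes[bundle.sample_index[pair.id2]]
        if pair.pair_type == "parent_offspring":
            segments = bundle.ibd.get(pair.pair_id) or _default_po_segments(pair.pair_id, chroms)
        else:
            segments = trim_segments(bundle.ibd.get(pair.pair_id, []), trim)
        for seg in segments:
            for c in classify_pair_segment(h1, h2, seg, pair.pair_type):
                if c.resolution not in _RESOLVED:
                    continue
                if pair.pair_type == "parent_offspring":
                    if c.shared is not None and c.not_shared:
                        tntc_d[c.snp_idx].append(c.shared - float(np.mean(c.not_shared)))
                elif seg.state == 1:
                    if c.shared is not None and c.not_shared:
                        wspc_d[c.snp_idx].append(c.shared - float(np.mean(c.not_shared)))
                elif seg.state == 2:
                    bspc2[c.snp_idx].append(float(np.mean(c.not_shared)))
                else:
                    bspc0[c.snp_idx].append(float(np.mean(c.not_shared)))

    f_sample = bundle.haplotypes.mean(axis=(0, 1))
    maf = np.minimum(f_sample, 1.0 - f_sample)
    keep = maf >= maf_min
    if exclusion_mask:
        pos = variants["pos"].to_numpy()
        for chrom, start, end in exclusion_mask:
            keep &= ~((chroms == chrom) & (pos >= start) & (pos < end))
    if not keep.any():
        raise ValueError("no SNPs retained after MAF filter and exclusion mask")

    rows = []
    for l in np.flatnonzero(keep):
        blocks = {
            "tntc": one_sample_block(np.asarray(tntc_d[l])),
            "wspc": one_sample_block(np.asarray(wspc_d[l])),
            "bspc": two_sample_block(np.asarray(bspc2[l]), np.asarray(bspc0[l])),
        }
        z = combine(blocks)
        row = {
            "snp_id": variants["id"].iloc[l],
            "chrom": variants["chrom"].iloc[l],
            "pos": variants["pos"].iloc[l],
            "a1": variants["a1"].iloc[l],
            "a2": variants["a2"].iloc[l],
            "maf": maf[l],
            "f_sample": f_sample[l],
            "combined_z": z,
            "p": 2.0 * norm.sf(abs(z)) if math.isfinite(z) else math.nan,
        }
        for name, b in blocks.items():
            row[f"{name}_freq_diff"] = b.freq_diff
            row[f"{name}_se"] = b.se
            row[f"{name}_t"] = b.t
            row[f"{name}_n"] = b.n_pairs
        rows.append(row)
    return pd.DataFrame(rows)
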