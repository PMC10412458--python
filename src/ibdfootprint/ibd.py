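"""IBD segment handling and shared/not-shared allele classification.

Works on observed (called) genotype data: trims segment ends to guard
against uncertainty in recombination breakpoints, looks up per-SNP IBD
state, and splits relative-pair genotypes into shared and not-shared
alleles.  For sib pairs in IBD state 1 there are five possible unordered
genotype combinations; all but the double heterozygote are resolved by
genotype arithmetic, while the double heterozygote is resolved from phased
haplotypes at the nearest SNP within the segment at which one individual is
heterozygous and the other homozygous.  Parent-offspring pairs are handled
with the same machinery: the transmitted allele plays the role of the
shared allele and the parent's untransmitted allele is the single
not-shared allele (the offspring's allele from the other parent is used by
no comparison).

All coordinates are 0-based, half-open SNP indices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "IbdSegment",
    "AlleleClassification",
    "RESOLUTION_DIRECT",
    "RESOLUTION_NEIGHBOR",
    "RESOLUTION_UNRESOLVED",
    "RESOLUTION_INCONSISTENT",
    "trim_segments",
    "nearest_informative_neighbor",
    "classify_sib_alleles",
    "classify_parent_offspring",
    "classify_pair_segment",
    "truth_segments",
]

RESOLUTION_DIRECT = "direct"
RESOLUTION_NEIGHBOR = "neighbor_phase"
RESOLUTION_UNRESOLVED = "unresolved"
RESOLUTION_INCONSISTENT = "mendelian_inconsistent"


@dataclass(frozen=True)
class IbdSegment:
    """A maximal run of SNPs with constant IBD state for one pair.

    ``start_idx``/``end_idx`` are 0-based half-open SNP indices into the
    variant table.
    """

    pair_id: str
    chrom: str
    start_idx: int
    end_idx: int
    state: int

    def __post_init__(self) -> None:
        if self.start_idx >= self.end_idx:
            raise ValueError(f"empty segment: [{self.start_idx}, {self.end_idx})")
        if self.state not in (0, 1, 2):
            raise ValueError(f"IBD state must be 0, 1 or 2; got {self.state!r}")

    @property
    def length(self) -> int:
        return self.end_idx - self.start_idx


@dataclass(frozen=True)
class AlleleClassification:
    """Shared / not-shared split of one pair's alleles at one SNP."""

    pair_id: str
    snp_idx: int
    shared: int | None
    not_shared: tuple[int, ...]
    resolution: str


def trim_segments(segments: Iterable[IbdSegment], trim: int = 250) -> list[IbdSegment]:
    """Shorten every segment by ``trim`` SNPs at each end.

    Segments of length <= 2*trim are removed entirely; SNPs inside trimmed
    margins contribute to no comparison for that pair.  Recombination
    breakpoint calls are least reliable at segment ends, which otherwise
    leak systematic misclassification into the allele tallies.
    """
    if trim < 0:
        raise ValueError("trim must be >= 0")
    out = []
    for seg in segments:
        if seg.length > 2 * trim:
            out.append(replace(seg, start_idx=seg.start_idx + trim, end_idx=seg.end_idx - trim))
    return out


def nearest_informative_neighbor(
    geno1: np.ndarray,
    geno2: np.ndarray,
    snp_idx: int,
    segment_bounds: tuple[int, int],
) -> int | None:
    """Nearest SNP in the segment at which exactly one individual is heterozygous.

    ``segment_bounds`` is the enclosing (trimmed) constant-IBD run as a
    half-open index window; the search never crosses it, because phase
    carries shared-haplotype information only within a constant-IBD run.
    Ties between equidistant candidates break toward the lower index.
    Returns None when no informative SNP exists in the window.
    """
    lo, hi = segment_bounds
    g1 = np.asarray(geno1[lo:hi])
    g2 = np.asarray(geno2[lo:hi])
    informative = np.flatnonzero((g1 == 1) ^ (g2 == 1)) + lo
    if informative.size == 0:
        return None
    dist = np.abs(informative - snp_idx)
    return int(informative[np.argmin(dist)])  # argmin takes the first (lower) on ties


def _direct_shared(g1: int, g2: int) -> int | None:
    """Shared allele forced by the genotype pair under IBD1; None if ambiguous/invalid."""
    if g1 == 1 and g2 == 1:
        return None
    s = 0 if (g1 == 0 or g2 == 0) else 1
    if (g1 - s) in (0, 1) and (g2 - s) in (0, 1):
        return s
    return None  # Mendelian-inconsistent with IBD1, e.g. {0/0, 1/1}


def _resolve_double_het(
    haps1: np.ndarray,
    haps2: np.ndarray,
    snp_idx: int,
    neighbor: int,
) -> int:
    """Shared allele at a double-het target from phase at an informative neighbor.

    At the neighbor exactly one individual is heterozygous; the homozygous
    one pins the shared allele there, and the heterozygous individual's
    haplotype carrying that allele is the shared haplotype, read off at the
    target SNP.
    """
    g1n = int(haps1[0, neighbor] + haps1[1, neighbor])
    het = haps1 if g1n == 1 else haps2
    hom = haps2 if g1n == 1 else haps1
    shared_at_neighbor = int(hom[0, neighbor])  # homozygous: both alleles equal
    hap_idx = 0 if int(het[0, neighbor]) == shared_at_neighbor else 1
    return int(het[hap_idx, snp_idx])


def classify_sib_alleles(
    haps1: np.ndarray,
    haps2: np.ndarray,
    snp_idx: int,
    ibd_state: int,
    segment_bounds: tuple[int, int] | None = None,
    pair_id: str = "",
) -> AlleleClassification:
    """Split a sib pair's alleles at one SNP according to its IBD state.

    ``haps1``/``haps2`` are the phased haplotypes of the two siblings,
    shape (2, L).  For IBD1 the result is one shared plus two not-shared
    alleles; the double-heterozygote case is resolved through
    :func:`nearest_informative_neighbor` (requiring ``segment_bounds``).
    IBD2 pairs contribute their two distinct-by-descent alleles and IBD0
    pairs all four alleles; both are reported in ``not_shared`` with
    ``shared=None`` since no split applies (they feed the between-pair
    comparison only).
    """
    g1 = int(haps1[0, snp_idx] + haps1[1, snp_idx])
    g2 = int(haps2[0, snp_idx] + haps2[1, snp_idx])
    if ibd_state == 2:
        if g1 != g2:
            return AlleleClassification(pair_id, snp_idx, None, (), RESOLUTION_INCONSISTENT)
        return AlleleClassification(
            pair_id, snp_idx, None, (int(haps1[0, snp_idx]), int(haps1[1, snp_idx])), RESOLUTION_DIRECT
        )
    if ibd_state == 0:
        alleles = (
            int(haps1[0, snp_idx]),
            int(haps1[1, snp_idx]),
            int(haps2[0, snp_idx]),
            int(haps2[1, snp_idx]),
        )
        return AlleleClassification(pair_id, snp_idx, None, alleles, RESOLUTION_DIRECT)

    shared = _direct_shared(g1, g2)
    if shared is not None:
        return AlleleClassification(
            pair_id, snp_idx, shared, (g1 - shared, g2 - shared), RESOLUTION_DIRECT
        )
    if g1 == 1 and g2 == 1:
        if segment_bounds is None:
            return AlleleClassification(pair_id, snp_idx, None, (), RESOLUTION_UNRESOLVED)
        geno1 = haps1[0] + haps1[1]
        geno2 = haps2[0] + haps2[1]
        neighbor = nearest_informative_neighbor(geno1, geno2, snp_idx, segment_bounds)
        if neighbor is None:
            return AlleleClassification(pair_id, snp_idx, None, (), RESOLUTION_UNRESOLVED)
        s = _resolve_double_het(haps1, haps2, snp_idx, neighbor)
        return AlleleClassification(pair_id, snp_idx, s, (1 - s, 1 - s), RESOLUTION_NEIGHBOR)
    return AlleleClassification(pair_id, snp_idx, None, (), RESOLUTION_INCONSISTENT)


def classify_parent_offspring(
    parent_haps: np.ndarray,
    offspring_haps: np.ndarray,
    snp_idx: int,
    segment_bounds: tuple[int, int] | None = None,
    pair_id: str = "",
) -> AlleleClassification:
    """Transmitted (T) / nontransmitted (NT) split for a parent-offspring pair.

    Returns ``shared`` = T and ``not_shared`` = (NT,).  The offspring's
    allele from the other parent is excluded.  A parent-offspring pair is
    IBD1 everywhere, so the double-heterozygote case uses the same
    informative-neighbor resolution as sib pairs, with the whole chromosome
    (or supplied bounds) as the search window.
    """
    gp = int(parent_haps[0, snp_idx] + parent_haps[1, snp_idx])
    go = int(offspring_haps[0, snp_idx] + offspring_haps[1, snp_idx])
    shared = _direct_shared(gp, go)
    if shared is not None:
        return AlleleClassification(pair_id, snp_idx, shared, (gp - shared,), RESOLUTION_DIRECT)
    if gp == 1 and go == 1:
        if segment_bounds is None:
            segment_bounds = (0, parent_haps.shape[1])
        genop = parent_haps[0] + parent_haps[1]
        genoo = offspring_haps[0] + offspring_haps[1]
        neighbor = nearest_informative_neighbor(genop, genoo, snp_idx, segment_bounds)
        if neighbor is None:
            return AlleleClassification(pair_id, snp_idx, None, (), RESOLUTION_UNRESOLVED)
        t = _resolve_double_het(parent_haps, offspring_haps, snp_idx, neighbor)
        return AlleleClassification(pair_id, snp_idx, t, (1 - t,), RESOLUTION_NEIGHBOR)
    return AlleleClassification(pair_id, snp_idx, None, (), RESOLUTION_INCONSISTENT)


def classify_pair_segment(
    haps1: np.ndarray,
    haps2: np.ndarray,
    segment: IbdSegment,
    pair_type: str = "sib",
) -> list[AlleleClassification]:
    """Classify every SNP of one (trimmed) segment for one pair."""
    bounds = (segment.start_idx, segment.end_idx)
    out = []
    for idx in range(segment.start_idx, segment.end_idx):
        if pair_type == "parent_offspring":
            out.append(classify_parent_offspring(haps1, haps2, idx, bounds, segment.pair_id))
        else:
            out.append(
                classify_sib_alleles(haps1, haps2, idx, segment.state, bounds, segment.pair_id)
            )
    return out


def truth_segments(
    ibd_state_row: np.ndarray,
    shared_parent_row: np.ndarray,
    chroms: Sequence[str],
    pair_id: str,
) -> list[IbdSegment]:
    """Exact IBD segments of one simulated sib pair.

    Runs are broken on any change of the transmission-origin pattern, not
    just of the IBD state: two adjacent IBD1 stretches sharing first the
    paternal and then the maternal haplotype are distinct segments, because
    the shared haplotype (and hence within-run phase information) changes.
    Chromosome boundaries always break runs.
    """
    L = len(ibd_state_row)
    chrom_arr = np.asarray(chroms, dtype=object)
    pattern = ibd_state_row.astype(np.int64) * 4 + shared_parent_row.astype(np.int64)
    breaks = [0]
    for l in range(1, L):
        if pattern[l] != pattern[l - 1] or chrom_arr[l] != chrom_arr[l - 1]:
            breaks.append(l)
    breaks.append(L)
    return [
        IbdSegment(
            pair_id=pair_id,
            chrom=str(chrom_arr[a]),
            start_idx=int(a),
            end_idx=int(b),
            state=int(ibd_state_row[a]),
        )
        for a, b in zip(breaks[:-1], breaks[1:])
    ]
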