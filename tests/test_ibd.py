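"""Segment trimming and shared/not-shared allele classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ibdfootprint import cohort_sim, ibd, io
from ibdfootprint.ibd import AlleleClassification, IbdSegment
from ibdfootprint.liability import LiabilityModel


def seg(start, end, state=1, pair="p1", chrom="1"):
    return IbdSegment(pair, chrom, start, end, state)


class TestTrimSegments:
    def test_chromosome_spanning_trim_removes_expected_positions(self):
        # one segment per chromosome over 22 chromosomes: 2 * 250 * 22 positions removed
        segments = [seg(0, 30_000, state=1, chrom=str(c)) for c in range(1, 23)]
        trimmed = ibd.trim_segments(segments, trim=250)
        removed = sum(s.length for s in segments) - sum(s.length for s in trimmed)
        assert removed == 2 * 250 * 22 == 11_000

    def test_short_segment_removed_entirely(self):
        assert ibd.trim_segments([seg(100, 500)], trim=250) == []

    def test_trim_zero_is_identity(self):
        segments = [seg(0, 100), seg(100, 130, state=2)]
        assert ibd.trim_segments(segments, trim=0) == segments

    def test_never_creates_overlap_never_grows(self):
        segments = [seg(0, 400), seg(400, 1000, state=2), seg(1000, 1500, state=0)]
        trimmed = ibd.trim_segments(segments, trim=50)
        assert sum(s.length for s in trimmed) <= sum(s.length for s in segments)
        for a, b in zip(trimmed, trimmed[1:]):
            assert a.end_idx <= b.start_idx

    @given(st.integers(min_value=0, max_value=300), st.integers(min_value=1, max_value=1000))
    @settings(deadline=None, max_examples=50)
    def test_length_arithmetic(self, trim, length):
        segments = [seg(10, 10 + length)]
        out = ibd.trim_segments(segments, trim=trim)
        if length > 2 * trim:
            assert out[0].length == length - 2 * trim
        else:
            assert out == []

    def test_negative_trim_rejected(self):
        with pytest.raises(ValueError):
            ibd.trim_segments([], trim=-1)


def haps_from_strings(*rows):
    """Two haplotype strings per individual, e.g. '0101', '0011'."""
    return np.array([[int(c) for c in r] for r in rows], dtype=np.int8)


class TestClassifySibAlleles:
    @pytest.mark.parametrize(
        "g1_haps, g2_haps, shared, not_shared",
        [
            (("0", "0"), ("0", "1"), 0, (0, 1)),  # {0/0, 0/1}
            (("1", "1"), ("0", "1"), 1, (1, 0)),  # {1/1, 0/1}
            (("0", "0"), ("0", "0"), 0, (0, 0)),
            (("1", "1"), ("1", "1"), 1, (1, 1)),
            (("0", "1"), ("1", "1"), 1, (0, 1)),  # {0/1, 1/1}
        ],
    )
    def test_direct_ibd1_combinations(self, g1_haps, g2_haps, shared, not_shared):
        h1, h2 = haps_from_strings(*g1_haps), haps_from_strings(*g2_haps)
        c = ibd.classify_sib_alleles(h1, h2, 0, ibd_state=1, segment_bounds=(0, 1))
        assert c.resolution == ibd.RESOLUTION_DIRECT
        assert c.shared == shared
        assert c.not_shared == not_shared

    def test_mendelian_inconsistency_flagged(self):
        h1, h2 = haps_from_strings("0", "0"), haps_from_strings("1", "1")
        c = ibd.classify_sib_alleles(h1, h2, 0, ibd_state=1, segment_bounds=(0, 1))
        assert c.resolution == ibd.RESOLUTION_INCONSISTENT

    def test_double_het_resolved_via_neighbor(self):
        # target idx 1: both sibs heterozygous; neighbor idx 0: sib1 het, sib2 hom 0/0.
        # shared allele at neighbor is 0, carried by sib1's second haplotype, whose
        # allele at the target is 0 -> shared allele 0.
        h1 = haps_from_strings("11", "00")  # hap0 = (1,1), hap1 = (0,0)
        h2 = haps_from_strings("01", "00")
        c = ibd.classify_sib_alleles(h1, h2, 1, ibd_state=1, segment_bounds=(0, 2))
        assert c.resolution == ibd.RESOLUTION_NEIGHBOR
        assert c.shared == 0
        assert c.not_shared == (1, 1)

    def test_double_het_resolved_via_other_sibs_phase(self):
        # neighbor informative through sib2 being het while sib1 is hom
        h1 = haps_from_strings("01", "00")
        h2 = haps_from_strings("01", "10")  # hap0 carries 0 at neighbor -> shared hap
        c = ibd.classify_sib_alleles(h1, h2, 1, ibd_state=1, segment_bounds=(0, 2))
        assert c.resolution == ibd.RESOLUTION_NEIGHBOR
        assert c.shared == 1

    def test_double_het_without_informative_neighbor_unresolved(self):
        h1 = haps_from_strings("11", "00")
        h2 = haps_from_strings("10", "01")
        c = ibd.classify_sib_alleles(h1, h2, 0, ibd_state=1, segment_bounds=(0, 2))
        assert c.resolution == ibd.RESOLUTION_UNRESOLVED
        assert c.shared is None

    def test_ibd2_contributes_two_distinct_alleles(self):
        h1 = haps_from_strings("1", "0")
        h2 = haps_from_strings("0", "1")
        c = ibd.classify_sib_alleles(h1, h2, 0, ibd_state=2)
        assert c.shared is None
        assert sorted(c.not_shared) == [0, 1]

    def test_ibd0_contributes_four_alleles(self):
        h1 = haps_from_strings("1", "0")
        h2 = haps_from_strings("1", "1")
        c = ibd.classify_sib_alleles(h1, h2, 0, ibd_state=0)
        assert len(c.not_shared) == 4
        assert sum(c.not_shared) == 3


class TestNearestInformativeNeighbor:
    def _genos(self):
        # informative where exactly one individual is het
        g1 = np.array([1, 0, 1, 1, 0, 1, 1])
        g2 = np.array([0, 0, 1, 1, 0, 1, 0])
        return g1, g2  # informative at 0 and 6

    def test_closer_side_wins(self):
        g1, g2 = self._genos()
        assert ibd.nearest_informative_neighbor(g1, g2, 2, (0, 7)) == 0
        assert ibd.nearest_informative_neighbor(g1, g2, 5, (0, 7)) == 6

    def test_tie_breaks_to_lower_index(self):
        g1, g2 = self._genos()
        assert ibd.nearest_informative_neighbor(g1, g2, 3, (0, 7)) == 0

    def test_search_respects_segment_bounds(self):
        g1, g2 = self._genos()
        assert ibd.nearest_informative_neighbor(g1, g2, 3, (1, 6)) is None


class TestClassifyParentOffspring:
    @pytest.mark.parametrize(
        "p_haps, o_haps, t, nt",
        [
            (("0", "1"), ("0", "0"), 0, 1),  # parent 0/1, offspring 0/0
            (("1", "1"), ("0", "1"), 1, 1),  # parent 1/1, offspring 0/1
            (("0", "0"), ("0", "1"), 0, 0),
        ],
    )
    def test_direct_cases(self, p_haps, o_haps, t, nt):
        c = ibd.classify_parent_offspring(haps_from_strings(*p_haps), haps_from_strings(*o_haps), 0)
        assert c.resolution == ibd.RESOLUTION_DIRECT
        assert c.shared == t
        assert c.not_shared == (nt,)

    def test_double_het_trio_oracle(self):
        """Neighbor resolution agrees with resolving via the other parent's genotype.

        Simulated trios where the other parent is homozygous pin down the
        transmitted allele exactly; the phase-based call must match at every
        resolvable double-het site.
        """
        model = LiabilityModel(alpha=0.5, sib_corr=0.25)
        snps = [cohort_sim.SnpSpec(0.5, 0.0, map_position=i * 2.0) for i in range(12)]
        cohort = cohort_sim.simulate_cohort(model, snps, 400, pair_type="parent_offspring", seed=33)
        haps = cohort.haplotypes
        checked = phase_breaks = 0
        for i in range(cohort.n_pairs):
            father, mother, off = haps[i, 0], haps[i, 1], haps[i, 2]
            gf, gm, go = father.sum(axis=0), mother.sum(axis=0), off.sum(axis=0)
            for l in range(12):
                if gf[l] == 1 and go[l] == 1 and gm[l] in (0, 2):
                    # trio resolution: offspring maternal allele is gm/2,
                    # so the paternally transmitted allele is go - gm/2
                    t_trio = int(go[l] - gm[l] // 2)
                    c = ibd.classify_parent_offspring(father, off, l, (0, 12))
                    if c.resolution != ibd.RESOLUTION_NEIGHBOR:
                        continue
                    nb = ibd.nearest_informative_neighbor(gf, go, l, (0, 12))
                    if cohort.pat_origin[i, 0, l] == cohort.pat_origin[i, 0, nb]:
                        # no paternal recombination between target and neighbor:
                        # the phase-based call must equal the trio resolution
                        assert c.shared == t_trio
                        checked += 1
                    else:
                        # an intervening crossover is exactly the phasing-error
                        # mechanism; the call may then be wrong
                        phase_breaks += 1
        assert checked > 50  # enough double-het sites actually exercised
        assert phase_breaks < 0.1 * checked

    def test_inconsistent_flagged(self):
        c = ibd.classify_parent_offspring(haps_from_strings("0", "0"), haps_from_strings("1", "1"), 0)
        assert c.resolution == ibd.RESOLUTION_INCONSISTENT


class TestTruthRecovery:
    def test_error_free_classification_recovers_truth_everywhere(self, small_sib_cohort, small_sib_bundle):
        """On clean data every resolved site matches truth; only neighbor-less
        double-hets are unresolved."""
        shared = small_sib_cohort.truth_shared_allele()
        total = mismatches = unresolved = 0
        for pair in small_sib_bundle.pairs.itertuples():
            i = int(pair.pair_id.removeprefix("pair"))
            h1 = small_sib_bundle.haplotypes[small_sib_bundle.sample_index[pair.id1]]
            h2 = small_sib_bundle.haplotypes[small_sib_bundle.sample_index[pair.id2]]
            for segment in small_sib_bundle.ibd[pair.pair_id]:
                if segment.state != 1:
                    continue
                for c in ibd.classify_pair_segment(h1, h2, segment):
                    total += 1
                    if c.resolution == ibd.RESOLUTION_UNRESOLVED:
                        unresolved += 1
                        # unresolved only when genuinely no informative neighbor
                        g1, g2 = h1.sum(axis=0), h2.sum(axis=0)
                        assert (
                            ibd.nearest_informative_neighbor(
                                g1, g2, c.snp_idx, (segment.start_idx, segment.end_idx)
                            )
                            is None
                        )
                    else:
                        assert c.resolution != ibd.RESOLUTION_INCONSISTENT
                        if c.shared != shared[i, c.snp_idx]:
                            mismatches += 1
        assert total > 500
        assert mismatches == 0

    def test_truth_segments_partition_and_match_state(self, small_sib_cohort):
        cohort = small_sib_cohort
        chroms = [s.chrom for s in cohort.snps]
        sp = cohort.shared_parent()
        for i in range(0, 50):
            segs = ibd.truth_segments(cohort.ibd_state[i], sp[i], chroms, f"pair{i}")
            covered = np.zeros(cohort.n_snps, dtype=bool)
            for s in segs:
                assert not covered[s.start_idx : s.end_idx].any()
                covered[s.start_idx : s.end_idx] = True
                assert (cohort.ibd_state[i, s.start_idx : s.end_idx] == s.state).all()
            assert covered.all()
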