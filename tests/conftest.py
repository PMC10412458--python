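"""Shared fixtures and helpers: small simulated cohorts and truth-level statistics."""

from __future__ import annotations

import numpy as np
import pytest

from ibdfootprint import association, cohort_sim, io
from ibdfootprint.cohort_sim import OFF1, OFF2
from ibdfootprint.liability import LiabilityModel


def truth_wspc_bspc_blocks(cohort, snp_index=0):
    """WSPC/BSPC comparison blocks from simulation truth (no classification step).

    Uses the tracked transmission origins to split alleles, exactly as an
    error-free classification would; serves as an independent route for
    calibration tests.
    """
    l = snp_index
    haps = cohort.haplotypes
    part = cohort.participates[:, OFF1:]
    both = part[:, 0] & part[:, 1]
    state = cohort.ibd_state[:, l]
    sp = cohort.shared_parent()[:, l]
    pat1, mat1 = haps[:, OFF1, 0, l], haps[:, OFF1, 1, l]
    pat2, mat2 = haps[:, OFF2, 0, l], haps[:, OFF2, 1, l]
    g1 = pat1.astype(float) + mat1
    g2 = pat2.astype(float) + mat2

    m1 = both & (state == 1)
    shared = np.where(sp == 1, pat1, mat1).astype(float)
    ns_mean = np.where(sp == 1, mat1 + mat2, pat1 + pat2) / 2.0
    wspc_block = association.one_sample_block((shared - ns_mean)[m1])

    m2 = both & (state == 2)
    m0 = both & (state == 0)
    bspc_block = association.two_sample_block(g1[m2] / 2.0, ((g1 + g2) / 4.0)[m0])
    return wspc_block, bspc_block


def truth_tntc_block(cohort, snp_index=0):
    """TNTC block for a parent-offspring cohort from transmission truth."""
    from ibdfootprint.cohort_sim import FATHER, MOTHER

    l = snp_index
    haps = cohort.haplotypes
    diffs = []
    for parent, origin, off_hap in (
        (FATHER, cohort.pat_origin[:, 0, l], haps[:, OFF1, 0, l]),
        (MOTHER, cohort.mat_origin[:, 0, l], haps[:, OFF1, 1, l]),
    ):
        mask = cohort.participates[:, parent] & cohort.participates[:, OFF1]
        nt = np.take_along_axis(haps[:, parent, :, l], (1 - origin)[:, None].astype(np.int64), axis=1)[:, 0]
        diffs.append(off_hap[mask].astype(float) - nt[mask])
    return association.one_sample_block(np.concatenate(diffs))


@pytest.fixture(scope="session")
def small_sib_cohort():
    """20-SNP linked sib cohort with one causal SNP, moderate ascertainment."""
    model = LiabilityModel(alpha=0.5, sib_corr=0.25)
    snps = [
        cohort_sim.SnpSpec(0.5, var_share=0.002 if i == 5 else 0.0, map_position=i * 5.0)
        for i in range(20)
    ]
    return cohort_sim.simulate_cohort(model, snps, 800, seed=11)


@pytest.fixture(scope="session")
def small_sib_bundle(small_sib_cohort):
    return io.cohort_to_bundle(small_sib_cohort)
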