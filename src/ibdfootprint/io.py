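"""Readers and writers for the formats the toolkit touches.

Phased haplotypes travel as VCF with pipe-separated GT; relative pairs,
IBD segments, summary statistics, score weights and phenotypes as TSV; and
genomic exclusion masks as BED (0-based half-open).  All internal
coordinates are 0-based; VCF positions are converted on the way in and out.
A :class:`DatasetBundle` holds one analysis-ready dataset (variants,
haplotype matrix, pair list, IBD segments, mask).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ibdfootprint.ibd import IbdSegment, truth_segments

logger = logging.getLogger("ibdfootprint")

__all__ = [
    "DatasetBundle",
    "read_phased_vcf",
    "write_phased_vcf",
    "read_pairs_tsv",
    "write_pairs_tsv",
    "read_ibd_tsv",
    "write_ibd_tsv",
    "read_summary_stats",
    "write_summary_stats",
    "read_weights_tsv",
    "read_mask_bed",
    "cohort_to_bundle",
    "write_run_manifest",
]

SUMMARY_COLUMNS = [
    "snp_id", "chrom", "pos", "a1", "a2", "maf", "f_sample",
    "tntc_freq_diff", "tntc_se", "tntc_t", "tntc_n",
    "wspc_freq_diff", "wspc_se", "wspc_t", "wspc_n",
    "bspc_freq_diff", "bspc_se", "bspc_t", "bspc_n",
    "combined_z", "p",
]


@dataclass
class DatasetBundle:
    """One analysis-ready dataset: variants, haplotypes, pairs, IBD, mask."""

    variants: pd.DataFrame  # chrom, pos, id, a1, a2
    haplotypes: np.ndarray  # (n_individuals, 2, L) int8
    samples: list[str]
    pairs: pd.DataFrame  # pair_id, id1, id2, pair_type
    ibd: dict[str, list[IbdSegment]] = field(default_factory=dict)
    mask: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sample_index = {s: i for i, s in enumerate(self.samples)}
        missing = [
            x
            for pair in self.pairs.itertuples()
            for x in (pair.id1, pair.id2)
            if x not in self.sample_index
        ]
        if missing:
            raise ValueError(f"pair members absent from haplotype samples: {missing[:5]}")
        L = self.haplotypes.shape[2]
        for segs in self.ibd.values():
            for seg in segs:
                if seg.end_idx > L:
                    raise ValueError(f"IBD segment {seg} exceeds variant count {L}")


def read_phased_vcf(path: str | Path) -> tuple[pd.DataFrame, np.ndarray, list[str], dict]:
    """Read a phased VCF into a variant table and haplotype matrix.

    Only biallelic records with fully phased GT are accepted; multiallelic
    or unphased records are skipped with a warning tally, returned as the
    fourth element.  Haplotype entries are 0 (REF) / 1 (ALT).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, haps = [], []
    skipped = {"multiallelic": 0, "unphased": 0, "missing": 0}
    for v in vcf:
        if len(v.ALT) != 1:
            skipped["multiallelic"] += 1
            continue
        gts = v.genotypes  # list of [a, b, phased]
        arr = np.asarray(gts, dtype=np.int64)
        if arr.shape[1] != 3 or not arr[:, 2].all():
            skipped["unphased"] += 1
            logger.warning("skipping unphased record %s:%s", v.CHROM, v.POS)
            continue
        if (arr[:, :2] < 0).any():
            skipped["missing"] += 1
            continue
        rows.append(
            {"chrom": v.CHROM, "pos": v.POS - 1, "id": v.ID or f"{v.CHROM}:{v.POS}",
             "a1": v.REF, "a2": v.ALT[0]}
        )
        haps.append(arr[:, :2].astype(np.int8))
    vcf.close()
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "a1", "a2"])
    if haps:
        hap_matrix = np.stack(haps, axis=2)  # (n, 2, L)
    else:
        hap_matrix = np.zeros((len(samples), 2, 0), dtype=np.int8)
    return variants, hap_matrix, samples, skipped


def write_phased_vcf(
    path: str | Path,
    variants: pd.DataFrame,
    haplotypes: np.ndarray,
    samples: list[str],
) -> None:
    """Write a haplotype matrix as a minimal phased VCF (text, uncompressed)."""
    n, _, L = haplotypes.shape
    if n != len(samples) or L != len(variants):
        raise ValueError("haplotype matrix shape does not match samples/variants")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for l, row in enumerate(variants.itertuples()):
            gts = "\t".join(f"{haplotypes[i, 0, l]}|{haplotypes[i, 1, l]}" for i in range(n))
            fh.write(f"{row.chrom}\t{row.pos + 1}\t{row.id}\t{row.a1}\t{row.a2}\t.\tPASS\t.\tGT\t{gts}\n")


def read_pairs_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "id1": str, "id2": str})
    required = {"pair_id", "id1", "id2", "pair_type"}
    if not required.issubset(df.columns):
        raise ValueError(f"pairs TSV must have columns {sorted(required)}")
    return df


def write_pairs_tsv(path: str | Path, pairs: pd.DataFrame) -> None:
    pairs.to_csv(path, sep="\t", index=False)


def read_ibd_tsv(path: str | Path) -> dict[str, list[IbdSegment]]:
    """IBD segments TSV (pair_id, chrom, start_idx, end_idx, state; 0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "chrom": str})
    out: dict[str, list[IbdSegment]] = {}
    for row in df.itertuples():
        out.setdefault(row.pair_id, []).append(
            IbdSegment(row.pair_id, row.chrom, int(row.start_idx), int(row.end_idx), int(row.state))
        )
    return out


def write_ibd_tsv(path: str | Path, ibd: dict[str, list[IbdSegment]]) -> None:
    rows = [
        {"pair_id": s.pair_id, "chrom": s.chrom, "start_idx": s.start_idx,
         "end_idx": s.end_idx, "state": s.state}
        for segs in ibd.values()
        for s in segs
    ]
    pd.DataFrame(rows, columns=["pair_id", "chrom", "start_idx", "end_idx", "state"]).to_csv(
        path, sep="\t", index=False
    )


def write_summary_stats(scan: pd.DataFrame, path: str | Path) -> None:
    """Write a scan table with the fixed summary-statistics header; NaN -> NA."""
    out = scan.reindex(columns=SUMMARY_COLUMNS)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"chrom": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-statistics file missing columns: {missing}")
    return df


def read_weights_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"snp_id", "weight"}.issubset(df.columns):
        raise ValueError("weights TSV must have columns snp_id, weight")
    return df


def read_mask_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a BED exclusion mask; returns merged, sorted half-open intervals."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: BED line needs >= 3 fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(f"{path}:{line_no}: start {start} >= end {end}")
            intervals.append((chrom, start, end))
    intervals.sort()
    merged: list[tuple[str, int, int]] = []
    for chrom, start, end in intervals:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            merged[-1] = (chrom, merged[-1][1], max(end, merged[-1][2]))
        else:
            merged.append((chrom, start, end))
    return merged


def _variant_table(snps) -> pd.DataFrame:
    rows = []
    within: dict[str, int] = {}
    for k, s in enumerate(snps):
        i = within.get(s.chrom, 0)
        within[s.chrom] = i + 1
        # 1 cM ~ 1 Mb; the within-chromosome index breaks position ties
        rows.append(
            {"chrom": s.chrom, "pos": int(round(s.map_position * 1_000_000)) + i,
             "id": f"snp{k}", "a1": "A", "a2": "B"}
        )
    return pd.DataFrame(rows, columns=["chrom", "pos", "id", "a1", "a2"])


def cohort_to_bundle(cohort, layer: str = "truth") -> DatasetBundle:
    """Export the ascertained pairs of a simulated cohort as a DatasetBundle.

    Only participating individuals appear (a real study observes nobody
    else): for sib cohorts, both-participating pairs with their truth IBD
    segments; for parent-offspring cohorts, each ascertained parent with
    the ascertained first offspring (two pairs when both parents
    participate).  ``layer`` selects truth or called haplotypes.
    """
    from ibdfootprint.cohort_sim import FATHER, MOTHER, OFF1, OFF2

    haps = cohort._haps(layer)
    variants = _variant_table(cohort.snps)
    chroms = [s.chrom for s in cohort.snps]

    samples: list[str] = []
    hap_rows: list[np.ndarray] = []
    pair_rows: list[dict] = []
    ibd: dict[str, list[IbdSegment]] = {}

    def add_individual(i: int, member: int, label: str) -> str:
        name = f"fam{i}_{label}"
        samples.append(name)
        hap_rows.append(haps[i, member])
        return name

    part = cohort.participates
    if cohort.pair_type == "sib":
        shared = cohort.shared_parent()
        for i in np.flatnonzero(part[:, OFF1] & part[:, OFF2]):
            id1 = add_individual(i, OFF1, "sib1")
            id2 = add_individual(i, OFF2, "sib2")
            pid = f"pair{i}"
            pair_rows.append({"pair_id": pid, "id1": id1, "id2": id2, "pair_type": "sib"})
            ibd[pid] = truth_segments(cohort.ibd_state[i], shared[i], chroms, pid)
    else:
        for i in range(cohort.n_pairs):
            if not part[i, OFF1]:
                continue
            off_id = None
            for member, label in ((FATHER, "father"), (MOTHER, "mother")):
                if part[i, member]:
                    if off_id is None:
                        off_id = add_individual(i, OFF1, "off")
                    pid = f"pair{i}_{label}"
                    par_id = add_individual(i, member, label)
                    pair_rows.append(
                        {"pair_id": pid, "id1": par_id, "id2": off_id, "pair_type": "parent_offspring"}
                    )
    if hap_rows:
        hap_matrix = np.stack(hap_rows, axis=0).astype(np.int8)
    else:
        hap_matrix = np.zeros((0, 2, len(chroms)), dtype=np.int8)
    pairs = pd.DataFrame(pair_rows, columns=["pair_id", "id1", "id2", "pair_type"])
    return DatasetBundle(variants=variants, haplotypes=hap_matrix, samples=samples, pairs=pairs, ibd=ibd)


def write_run_manifest(path: str | Path, parameters: dict) -> None:
    """Machine-readable record of a run: parameters, their hash, versions."""
    from ibdfootprint import __version__

    payload = {
        "package": "ibdfootprint",
        "version": __version__,
        "numpy": np.__version__,
        "parameters": parameters,
    }
    payload["parameter_hash"] = hashlib.sha256(
        json.dumps(parameters, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
        fh.write("\n")
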