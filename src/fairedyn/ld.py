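"""Linkage disequilibrium from phased haplotypes and SNP-peak association.

r-squared is the squared allelic correlation D^2 / (pA qA pB qB) computed
directly over founder haplotype columns; disease relevance of an
accessible region is tiered as *strong* (a disease-associated SNP lies in
the peak itself) or *putative* (a SNP in the peak is in strong LD,
r^2 >= 0.8 by default, with a disease-associated SNP).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenomicInterval


@dataclass
class HaplotypePanel:
    """Biallelic SNPs x phased haplotypes, alleles coded 0/1."""

    haplotype_ids: list[str]
    snps: pd.DataFrame  # columns: rsid, chrom, pos, ref, alt
    alleles: np.ndarray  # H x S over {0,1}
    n_skipped: int = 0
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.uint8)
        n_hap, n_snp = self.alleles.shape
        if n_hap != len(self.haplotype_ids):
            raise ValueError("allele matrix rows != number of haplotypes")
        if n_snp != len(self.snps):
            raise ValueError("allele matrix columns != number of SNPs")
        if n_hap < 4:
            raise ValueError("need at least 4 haplotypes")
        rsids = self.snps["rsid"]
        if rsids.duplicated().any():
            dups = rsids[rsids.duplicated()].tolist()
            raise ValueError(f"duplicate rsIDs in panel: {dups}")
        self.snps = self.snps.reset_index(drop=True)
        self._index = {r: i for i, r in enumerate(self.snps["rsid"])}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def column(self, rsid: str) -> np.ndarray:
        if rsid not in self._index:
            raise KeyError(f"unknown rsID {rsid}")
        return self.alleles[:, self._index[rsid]]

    def is_monomorphic(self, rsid: str) -> bool:
        col = self.column(rsid)
        return bool(col.min() == col.max())


def r_squared(panel: HaplotypePanel, rsid1: str, rsid2: str) -> float:
    """Squared LD correlation between two SNPs over the panel's haplotypes.

    With allele-1 frequencies pA, pB and joint frequency pAB,
    D = pAB - pA*pB and r^2 = D^2 / (pA(1-pA) pB(1-pB)). Symmetric and
    invariant to flipping either SNP's allele coding.
    """
    a = panel.column(rsid1).astype(float)
    b = panel.column(rsid2).astype(float)
    p_a, p_b = a.mean(), b.mean()
    if p_a in (0.0, 1.0):
        raise ValueError(f"r^2 undefined: {rsid1} is monomorphic")
    if p_b in (0.0, 1.0):
        raise ValueError(f"r^2 undefined: {rsid2} is monomorphic")
    p_ab = float((a * b).mean())
    d = p_ab - p_a * p_b
    return float(d * d / (p_a * (1 - p_a) * p_b * (1 - p_b)))


def snps_in_peaks(snps: pd.DataFrame, peaks: list[tuple[GenomicInterval, str]]) -> pd.DataFrame:
    """Intersect SNP positions with labeled peaks (half-open, start inclusive).

    ``snps`` needs columns rsid/chrom/pos; ``peaks`` pairs each interval
    with its dynamics class label. One output row per (SNP, peak) hit.
    """
    rows = []
    for iv, class_label in peaks:
        on_chrom = snps[snps["chrom"] == iv.chrom]
        hit = on_chrom[(on_chrom["pos"] >= iv.start) & (on_chrom["pos"] < iv.end)]
        for _, snp in hit.iterrows():
            rows.append(
                {
                    "rsid": snp["rsid"],
                    "chrom": snp["chrom"],
                    "pos": int(snp["pos"]),
                    "peak_chrom": iv.chrom,
                    "peak_start": iv.start,
                    "peak_end": iv.end,
                    "peak_class": class_label,
                }
            )
    columns = ["rsid", "chrom", "pos", "peak_chrom", "peak_start", "peak_end", "peak_class"]
    return pd.DataFrame(rows, columns=columns)


LD_REPORT_COLUMNS = [
    "peak_chrom", "peak_start", "peak_end", "peak_class",
    "snp_in_peak", "allergy_snp", "r2", "evidence_tier", "association",
]


def ld_expand(
    in_peak_snps: pd.DataFrame,
    disease_catalog: pd.DataFrame,
    panel: HaplotypePanel,
    r2_min: float = 0.8,
    region: GenomicInterval | None = None,
) -> pd.DataFrame:
    """Associate in-peak SNPs with disease SNPs directly or through LD.

    Emits a *strong* row (r2 = NA) when the in-peak SNP is itself in the
    disease catalog, and a *putative* row for every disease SNP with
    r^2 >= ``r2_min``. ``region`` restricts the disease-SNP search (the
    TAD-confinement used for tractability). Rows are ordered by peak,
    strong first, then descending r2. rsIDs absent from the panel are
    skipped and reported in the ``skipped`` attribute of the result.
    """
    if disease_catalog.empty:
        raise ValueError("disease catalog is empty")
    catalog = disease_catalog
    if region is not None:
        catalog = catalog[
            (catalog["chrom"] == region.chrom)
            & (catalog["pos"] >= region.start)
            & (catalog["pos"] < region.end)
        ]
    trait_of = dict(zip(catalog["rsid"], catalog["trait"]))
    skipped: list[str] = []
    rows = []
    for _, rec in in_peak_snps.iterrows():
        rsid = rec["rsid"]
        peak_key = (rec["peak_chrom"], rec["peak_start"], rec["peak_end"])
        base = {
            "peak_chrom": peak_key[0],
            "peak_start": peak_key[1],
            "peak_end": peak_key[2],
            "peak_class": rec["peak_class"],
            "snp_in_peak": rsid,
        }
        if rsid in trait_of:
            rows.append(
                base | {
                    "allergy_snp": rsid,
                    "r2": np.nan,  # printed as NA: self-pair
                    "evidence_tier": "strong",
                    "association": trait_of[rsid],
                }
            )
        if rsid not in panel:
            skipped.append(rsid)
            continue
        if panel.is_monomorphic(rsid):
            skipped.append(rsid)
            continue
        for _, dis in catalog.iterrows():
            dis_rsid = dis["rsid"]
            if dis_rsid == rsid:
                continue
            if dis_rsid not in panel:
                skipped.append(dis_rsid)
                continue
            if panel.is_monomorphic(dis_rsid):
                continue
            r2 = r_squared(panel, rsid, dis_rsid)
            if r2 >= r2_min:
                rows.append(
                    base | {
                        "allergy_snp": dis_rsid,
                        "r2": r2,
                        "evidence_tier": "putative",
                        "association": dis["trait"],
                    }
                )
    result = pd.DataFrame(rows, columns=LD_REPORT_COLUMNS)
    if not result.empty:
        tier_rank = result["evidence_tier"].map({"strong": 0, "putative": 1})
        result = (
            result.assign(_tier=tier_rank)
            .sort_values(
                ["peak_chrom", "peak_start", "_tier", "r2"],
                ascending=[True, True, True, False],
                kind="stable",
            )
            .drop(columns="_tier")
            .reset_index(drop=True)
        )
    result.attrs["skipped"] = sorted(set(skipped))
    return result


def format_ld_report(report: pd.DataFrame) -> pd.DataFrame:
    """Render r2 with the NA convention for self-pairs, for TSV output."""
    out = report.copy()
    out["r2"] = [
        "NA" if pd.isna(v) else f"{v:.4g}" for v in report["r2"]
    ]
    return out
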