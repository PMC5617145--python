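"""Fractional-overlap set algebra over peak sets: condition-dynamics
classification, nearest-gene annotation, Venn accounting, regulatory
domains, and generic gene-set enrichment.

The two overlap rules mirror interval-tool semantics: a peak is
*present* in a set when some member covers at least 25% of the peak's
length, and *absent* from an exclusion set when every member covers
less than 10% of it. Both fractions are of the query peak (asymmetric).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GeneModel, GenomicInterval
from .peakcall import PeakSet

logger = logging.getLogger(__name__)


def overlap_fraction(a: GenomicInterval, b: GenomicInterval) -> float:
    """Fraction of ``a`` covered by ``b`` (asymmetric); 0 across chromosomes."""
    return a.overlap_length(b) / len(a)


class _SetIndex:
    """Interval-tree index over a peak collection for max-overlap queries."""

    def __init__(self, peaks):
        self.trees: dict[str, IntervalTree] = {}
        for iv in peaks:
            self.trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)

    def max_fraction(self, peak: GenomicInterval) -> float:
        tree = self.trees.get(peak.chrom)
        if not tree:
            return 0.0
        best = 0
        for hit in tree.overlap(peak.start, peak.end):
            ov = min(peak.end, hit.end) - max(peak.start, hit.begin)
            if ov > best:
                best = ov
        return best / len(peak)


def present_in(peak: GenomicInterval, peaks, f: float = 0.25) -> bool:
    """True iff some set member covers at least fraction ``f`` of the peak."""
    index = peaks if isinstance(peaks, _SetIndex) else _SetIndex(peaks)
    return index.max_fraction(peak) >= f


def absent_from(peak: GenomicInterval, peak_sets, f: float = 0.10) -> bool:
    """True iff every exclusion set covers less than fraction ``f`` of the
    peak ("at least 10% overlap" triggers exclusion, so exactly 10% is
    not absent)."""
    for peaks in peak_sets:
        index = peaks if isinstance(peaks, _SetIndex) else _SetIndex(peaks)
        if index.max_fraction(peak) >= f:
            return False
    return True


@dataclass
class ClassificationRule:
    class_name: str
    require_present: tuple[str, ...] = ()
    require_absent: tuple[str, ...] = ()
    presence_fraction: float = 0.25
    absence_fraction: float = 0.10
    decoy_filter: str = "none"  # none | exclude_any | require_at_least_k
    k: int = 0

    def __post_init__(self) -> None:
        if set(self.require_present) & set(self.require_absent):
            raise ValueError(f"rule {self.class_name}: present/absent labels overlap")
        if not 0 < self.presence_fraction <= 1 or not 0 < self.absence_fraction <= 1:
            raise ValueError(f"rule {self.class_name}: fractions must be in (0, 1]")
        if self.decoy_filter not in ("none", "exclude_any", "require_at_least_k"):
            raise ValueError(f"rule {self.class_name}: bad decoy_filter {self.decoy_filter!r}")


def fig3_rules(strict_epidermal: bool = False) -> list[ClassificationRule]:
    """The five-class taxonomy of condition dynamics, decoys excluded.

    ``strict_epidermal`` additionally requires Graft for the Epidermal
    class; the default leaves Graft unconstrained.
    """
    epidermal_present = ("Keratinocyte", "ESS", "Graft") if strict_epidermal else (
        "Keratinocyte", "ESS")
    mk = lambda name, pres, abst: ClassificationRule(
        name, pres, abst, decoy_filter="exclude_any")
    return [
        mk("Epidermal", epidermal_present, ()),
        mk("ThreeD", ("ESS", "Graft"), ("Keratinocyte",)),
        mk("Stable", ("Graft", "TapeStrip"), ("ESS",)),
        mk("IntactBarrier", ("Graft",), ("ESS", "TapeStrip")),
        mk("BarrierDeficient", ("ESS", "TapeStrip"), ("Graft",)),
    ]


def fig5_rules() -> list[ClassificationRule]:
    """TAD-scale taxonomy: housekeeping regions shared with at least 3
    decoy cell types, then decoy-excluded epidermal/3D/barrier classes."""
    all4 = ("Keratinocyte", "ESS", "Graft", "TapeStrip")
    return [
        ClassificationRule("Housekeeping", all4, (), decoy_filter="require_at_least_k", k=3),
        ClassificationRule("Epidermal", all4, (), decoy_filter="exclude_any"),
        ClassificationRule("ThreeD", ("ESS", "Graft", "TapeStrip"), ("Keratinocyte",),
                           decoy_filter="exclude_any"),
        ClassificationRule("BarrierDeficient", ("ESS", "TapeStrip"),
                           ("Graft", "Keratinocyte"), decoy_filter="exclude_any"),
    ]


@dataclass
class ClassifiedPeak:
    peak: GenomicInterval
    class_name: str  # "Unclassified" when no rule matches
    origin: str  # condition set the candidate came from
    n_matching_rules: int = 1


@dataclass
class ClassificationResult:
    peaks: list[ClassifiedPeak]
    counts: dict[str, int]
    n_multi_match: int

    def by_class(self, class_name: str) -> list[GenomicInterval]:
        return [cp.peak for cp in self.peaks if cp.class_name == class_name]


def classify_peaks(
    condition_sets: dict[str, PeakSet | list],
    decoy_sets: list[PeakSet | list],
    rules: list[ClassificationRule],
) -> ClassificationResult:
    """Assign each candidate peak its first matching dynamics class.

    The candidate universe is the union of all condition peaks
    (deduplicated by exact interval identity). Rules are applied in
    declared order; peaks matching several rules keep the first and are
    tallied in ``n_multi_match``.
    """
    def as_list(s):
        return s.peaks if isinstance(s, PeakSet) else list(s)

    condition_peaks = {label: as_list(s) for label, s in condition_sets.items()}
    for rule in rules:
        for label in rule.require_present + rule.require_absent:
            if label not in condition_peaks:
                raise ValueError(f"rule {rule.class_name} references unknown label {label!r}")
    indices = {label: _SetIndex(peaks) for label, peaks in condition_peaks.items()}
    decoy_indices = [_SetIndex(as_list(s)) for s in decoy_sets]

    candidates: list[tuple[GenomicInterval, str]] = []
    seen: set[tuple[str, int, int]] = set()
    for label in condition_peaks:
        for iv in condition_peaks[label]:
            key = (iv.chrom, iv.start, iv.end)
            if key not in seen:
                seen.add(key)
                candidates.append((iv, label))

    classified: list[ClassifiedPeak] = []
    counts = {rule.class_name: 0 for rule in rules}
    counts["Unclassified"] = 0
    n_multi = 0
    for iv, origin in candidates:
        matches = []
        for rule in rules:
            ok = all(
                indices[lab].max_fraction(iv) >= rule.presence_fraction
                for lab in rule.require_present
            ) and all(
                indices[lab].max_fraction(iv) < rule.absence_fraction
                for lab in rule.require_absent
            )
            if ok and rule.decoy_filter == "exclude_any":
                ok = all(d.max_fraction(iv) < rule.absence_fraction for d in decoy_indices)
            elif ok and rule.decoy_filter == "require_at_least_k":
                n_hit = sum(
                    d.max_fraction(iv) >= rule.presence_fraction for d in decoy_indices
                )
                ok = n_hit >= rule.k
            if ok:
                matches.append(rule.class_name)
        name = matches[0] if matches else "Unclassified"
        if len(matches) > 1:
            n_multi += 1
        counts[name] += 1
        classified.append(ClassifiedPeak(iv, name, origin, n_matching_rules=len(matches)))
    if n_multi:
        logger.info("classify_peaks: %d peaks matched more than one rule (first kept)", n_multi)
    return ClassificationResult(peaks=classified, counts=counts, n_multi_match=n_multi)


# ---------------------------------------------------------------------------
# Gene annotation


@dataclass
class NearestGeneRecord:
    peak: GenomicInterval
    gene_id: str | None
    distance: int | None  # signed: negative = upstream of the TSS
    tie: bool = False


def nearest_gene(peak: GenomicInterval, genes: list[GeneModel]) -> NearestGeneRecord:
    """Gene whose TSS is closest to the peak center; ties to the smaller
    coordinate (flagged). Distance is signed by gene strand, negative
    upstream."""
    on_chrom = [g for g in genes if g.chrom == peak.chrom]
    if not on_chrom:
        return NearestGeneRecord(peak, None, None)
    center = peak.center
    best = min(on_chrom, key=lambda g: (abs(center - g.tss), g.tss))
    dmin = abs(center - best.tss)
    tie = sum(1 for g in on_chrom if abs(center - g.tss) == dmin) > 1
    signed = (center - best.tss) if best.strand == "+" else (best.tss - center)
    return NearestGeneRecord(peak, best.gene_id, signed, tie=tie)


def annotate_peaks(peaks, genes: list[GeneModel]) -> pd.DataFrame:
    rows = []
    for iv in peaks:
        rec = nearest_gene(iv, genes)
        rows.append(
            {
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "gene_id": rec.gene_id, "distance": rec.distance, "tie": rec.tie,
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id", "distance", "tie"])


def gene_overlap_sets(assignments: dict[str, list[str]]) -> dict:
    """Venn-region counts over per-sample gene lists plus the 'uncommon'
    lists (each sample's genes minus those common to all samples)."""
    if len(assignments) < 2:
        raise ValueError("need at least 2 samples")
    sets = {label: set(genes) for label, genes in assignments.items()}
    labels = list(sets)
    common = set.intersection(*sets.values())
    regions: dict[frozenset, int] = {}
    universe = set.union(*sets.values())
    for gene in universe:
        membership = frozenset(lab for lab in labels if gene in sets[lab])
        regions[membership] = regions.get(membership, 0) + 1
    return {
        "region_counts": regions,
        "common": common,
        "uncommon": {lab: sets[lab] - common for lab in labels},
        "union_size": len(universe),
    }


# ---------------------------------------------------------------------------
# Regulatory domains (basal + extension)


@dataclass
class RegulatoryDomain:
    gene_id: str
    basal: GenomicInterval
    extended: GenomicInterval


def build_regulatory_domains(
    genes: list[GeneModel],
    chrom_sizes: dict[str, int],
    basal_up: int = 5000,
    basal_down: int = 1000,
    max_ext: int = 1_000_000,
) -> list[RegulatoryDomain]:
    """Basal window around each TSS, extended up to ``max_ext`` but
    stopping at neighboring genes' basal domains (never shrinking below
    the gene's own basal window). Chromosome ends clip."""
    domains: list[RegulatoryDomain] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, chrom_genes in by_chrom.items():
        L = chrom_sizes[chrom]
        chrom_genes = sorted(chrom_genes, key=lambda g: g.tss)
        basals = []
        for g in chrom_genes:
            if g.strand == "+":
                b = (max(0, g.tss - basal_up), min(L, g.tss + basal_down))
            else:
                b = (max(0, g.tss - basal_down), min(L, g.tss + basal_up))
            basals.append(b)
        for i, g in enumerate(chrom_genes):
            b_start, b_end = basals[i]
            ext_start = max(0, g.tss - max_ext)
            ext_end = min(L, g.tss + max_ext)
            prev_ends = [basals[j][1] for j in range(len(chrom_genes)) if j != i
                         and basals[j][1] <= b_start]
            next_starts = [basals[j][0] for j in range(len(chrom_genes)) if j != i
                           and basals[j][0] >= b_end]
            if prev_ends:
                ext_start = max(ext_start, max(prev_ends))
            if next_starts:
                ext_end = min(ext_end, min(next_starts))
            ext_start = min(ext_start, b_start)
            ext_end = max(ext_end, b_end)
            domains.append(
                RegulatoryDomain(
                    g.gene_id,
                    basal=GenomicInterval(chrom, b_start, b_end, name=g.gene_id),
                    extended=GenomicInterval(chrom, ext_start, ext_end, name=g.gene_id),
                )
            )
    return domains


# ---------------------------------------------------------------------------
# Generic gene-set enrichment


def geneset_enrichment(
    foreground: set[str],
    universe: set[str],
    gmt_sets: dict[str, set[str]],
    min_set: int = 30,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of a gene list against GMT
    sets, Benjamini-Hochberg corrected; sets with fewer than ``min_set``
    genes in the universe are dropped."""
    if not universe:
        raise ValueError("empty universe")
    foreground = set(foreground)
    if not foreground <= universe:
        raise ValueError("foreground must be a subset of the universe")
    N, n = len(universe), len(foreground)
    rows = []
    for set_name, genes in gmt_sets.items():
        in_universe = genes & universe
        K = len(in_universe)
        if K < min_set:
            continue
        k = len(in_universe & foreground)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": set_name, "set_size": K, "overlap": k, "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p_value"])
    if df.empty:
        df["q_value"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
        return df
    _, q, _, _ = multipletests(df["p_value"], method="fdr_bh")
    df["q_value"] = q
    df["significant"] = df["q_value"] < fdr
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)
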