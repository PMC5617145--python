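"""Synthetic data emulating a four-condition epidermal FAIRE experiment.

The generator produces a small random genome, plants non-overlapping
truth peaks realizing the condition-dynamics classes (Epidermal, 3D,
Stable, Intact-barrier, Barrier-deficient, Housekeeping, Decoy), draws
FAIRE-like fragments (150-600 bp) from a piecewise-constant Poisson
intensity enriched inside peaks present in each condition, writes a
motif consensus into barrier-deficient peaks, and builds an LD-block
haplotype panel with designated peak/disease SNP pairs. Everything is a
pure function of (config, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenomeAssembly, GeneModel, GenomicInterval
from .ld import HaplotypePanel
from .motifs import MotifMatrix, reverse_complement
from .peakcall import FragmentSet

CONDITIONS = ("Keratinocyte", "ESS", "Graft", "TapeStrip")
DECOY_CONDITIONS = ("HUVEC", "HepG2", "GM12878", "SmallIntestine")

# Which samples each truth class is open in. Decoy presence is the number
# of non-epidermal decoy sets carrying the peak.
CLASS_TABLE: dict[str, tuple[frozenset[str], int]] = {
    # class -> (epidermal conditions present, n decoy sets present)
    "Epidermal": (frozenset({"Keratinocyte", "ESS"}), 0),
    "ThreeD": (frozenset({"ESS", "Graft", "TapeStrip"}), 0),
    "Stable": (frozenset({"Graft", "TapeStrip"}), 0),
    "IntactBarrier": (frozenset({"Graft"}), 0),
    "BarrierDeficient": (frozenset({"ESS", "TapeStrip"}), 0),
    "Housekeeping": (frozenset(CONDITIONS), len(DECOY_CONDITIONS)),
    "Decoy": (frozenset(), len(DECOY_CONDITIONS)),
}

DYNAMIC_CLASSES = ("Epidermal", "ThreeD", "Stable", "IntactBarrier", "BarrierDeficient")


@dataclass
class TruthPeak:
    """A planted accessible region with its known condition pattern."""

    interval: GenomicInterval
    class_label: str
    presence: dict[str, bool]
    motif_planted: bool = False


@dataclass
class SimulationConfig:
    """Shape and rates of the synthetic experiment.

    Defaults give ~800 kb of genome, 30 peaks per class at 400 bp,
    0.01 background fragments/bp with 12x enrichment inside open peaks,
    and a 200-haplotype panel in 20 LD blocks.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length: int = 400_000
    gc: float = 0.41
    peaks_per_class: int = 30
    peak_width: int = 400
    background_rate: float = 0.01
    enrichment: float = 12.0
    frag_len_range: tuple[int, int] = (150, 600)
    motif_plant_rate: float = 0.8
    contamination_rate: float = 0.05  # mouse-tagged fragments in Graft/TapeStrip
    # haplotype panel
    n_haplotypes: int = 200
    n_blocks: int = 20
    snps_per_block: int = 10
    maf_range: tuple[float, float] = (0.1, 0.5)
    block_copy_prob: float = 0.9
    ld_planted_blocks: int = 8  # blocks whose peak/disease SNP pair has true r^2 = 1

    def validate(self) -> None:
        if not 0 <= self.gc <= 1:
            raise ValueError("gc must be in [0, 1]")
        if self.frag_len_range[0] < 1 or self.frag_len_range[0] > self.frag_len_range[1]:
            raise ValueError("invalid frag_len_range")
        if self.background_rate < 0 or self.enrichment < 0:
            raise ValueError("rates must be >= 0")
        if not 0 <= self.motif_plant_rate <= 1:
            raise ValueError("motif_plant_rate must be in [0, 1]")
        if self.n_haplotypes < 4:
            raise ValueError("n_haplotypes must be >= 4")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")


def _sub_seed(seed: int, *labels) -> np.random.Generator:
    """Deterministic stream per (seed, labels); stable across runs."""
    key = zlib.crc32(":".join(str(x) for x in labels).encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, key]))


def simulate_genome(config: SimulationConfig) -> GenomeAssembly:
    """I.i.d. sequence at the configured GC fraction."""
    config.validate()
    rng = _sub_seed(config.seed, "genome")
    p = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2])
    bases = np.frombuffer(b"ACGT", dtype="S1")
    sequence = {}
    sizes = {}
    for i in range(config.n_chrom):
        chrom = f"chr{i + 1}"
        draw = rng.choice(bases, size=config.chrom_length, p=p)
        sequence[chrom] = draw.tobytes().decode()
        sizes[chrom] = config.chrom_length
    return GenomeAssembly(sizes, sequence=sequence)


def plant_truth_peaks(genome: GenomeAssembly, config: SimulationConfig) -> list[TruthPeak]:
    """Place non-overlapping truth peaks for every class, uniformly.

    Pairwise gaps are at least twice the maximum fragment length so
    fragments from one peak cannot bleed into a neighbor.
    """
    config.validate()
    rng = _sub_seed(config.seed, "truth_peaks")
    min_gap = 2 * config.frag_len_range[1]
    classes = list(CLASS_TABLE)
    n_total = config.peaks_per_class * len(classes)
    labels = np.repeat(classes, config.peaks_per_class)
    rng.shuffle(labels)

    chroms = sorted(genome.chrom_sizes)
    # allocate peak counts proportionally to chromosome length
    lengths = np.array([genome.chrom_sizes[c] for c in chroms], dtype=float)
    alloc = np.floor(lengths / lengths.sum() * n_total).astype(int)
    for i in range(n_total - alloc.sum()):
        alloc[i % len(alloc)] += 1
    required = alloc * (config.peak_width + min_gap)
    for c, need, have in zip(chroms, required, lengths):
        if need > have:
            raise ValueError(
                f"genome too small: {c} needs >= {int(need)} bp for "
                f"{int(need / (config.peak_width + min_gap))} peaks, has {int(have)}"
            )
    truth: list[TruthPeak] = []
    idx = 0
    for chrom, n_here in zip(chroms, alloc):
        L = genome.chrom_sizes[chrom]
        slack = L - n_here * config.peak_width - (n_here - 1) * min_gap
        offsets = np.sort(rng.integers(0, slack + 1, size=n_here))
        for k in range(n_here):
            start = int(offsets[k] + k * (config.peak_width + min_gap))
            iv = GenomicInterval(chrom, start, start + config.peak_width,
                                 name=f"truth{idx:04d}")
            label = str(labels[idx])
            present_epi, n_decoy = CLASS_TABLE[label]
            presence = {c: c in present_epi for c in CONDITIONS}
            presence.update({d: j < n_decoy for j, d in enumerate(DECOY_CONDITIONS)})
            truth.append(TruthPeak(interval=iv, class_label=label, presence=presence))
            idx += 1
    return truth


def simulate_fragments(
    genome: GenomeAssembly,
    truth: list[TruthPeak],
    condition: str,
    config: SimulationConfig,
    replicate: int = 0,
) -> FragmentSet:
    """Draw FAIRE fragments for one condition (or decoy cell type).

    Fragment midpoints follow a Poisson intensity: ``background_rate``
    everywhere plus ``(enrichment - 1) x background_rate`` inside peaks
    present in this condition. Lengths are uniform on
    ``frag_len_range``; fragments are clipped to chromosome bounds.
    Graft/TapeStrip samples carry mouse-tagged contaminant fragments at
    ``contamination_rate`` (the xenograft neighborhood).
    """
    config.validate()
    if condition not in CONDITIONS + DECOY_CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    rng = _sub_seed(config.seed, "fragments", condition, replicate)
    fmin, fmax = config.frag_len_range
    fragments: list[GenomicInterval] = []
    midpoints: list[tuple[str, int]] = []
    for chrom in sorted(genome.chrom_sizes):
        L = genome.chrom_sizes[chrom]
        n_bg = rng.poisson(config.background_rate * L)
        mids = rng.integers(0, L, size=n_bg)
        midpoints.extend((chrom, int(m)) for m in mids)
    extra_rate = (config.enrichment - 1.0) * config.background_rate
    for peak in truth:
        if not peak.presence.get(condition, False):
            continue
        iv = peak.interval
        n_extra = rng.poisson(extra_rate * len(iv))
        mids = rng.integers(iv.start, iv.end, size=n_extra)
        midpoints.extend((iv.chrom, int(m)) for m in mids)
    lengths = rng.integers(fmin, fmax + 1, size=len(midpoints))
    for (chrom, mid), flen in zip(midpoints, lengths):
        L = genome.chrom_sizes[chrom]
        start = max(0, mid - int(flen) // 2)
        end = min(L, start + int(flen))
        if end > start:
            fragments.append(GenomicInterval(chrom, start, end))
    tags = None
    if condition in ("Graft", "TapeStrip") and config.contamination_rate > 0:
        contaminated = rng.random(len(fragments)) < config.contamination_rate
        tags = ["mouse" if c else "human" for c in contaminated]
    order = sorted(range(len(fragments)),
                   key=lambda i: (fragments[i].chrom, fragments[i].start, fragments[i].end))
    fragments_sorted = [fragments[i] for i in order]
    if tags is not None:
        tags = [tags[i] for i in order]
    return FragmentSet(sample=condition, fragments=fragments_sorted, source_tags=tags)


def ap1_like_motif(name: str = "AP1_synthetic", length_pad: float = 0.97) -> MotifMatrix:
    """Synthetic stand-in for an AP-1 family PWM (TGACTCA consensus)."""
    consensus = "TGACTCA"
    probs = np.full((len(consensus), 4), (1 - length_pad) / 3)
    for i, b in enumerate(consensus):
        probs[i, "ACGT".index(b)] = length_pad
    return MotifMatrix(name=name, probs=probs, tf_family="bZIP")


def make_motif_library(n_decoys: int, seed: int, length_range=(8, 12)) -> list[MotifMatrix]:
    """Random sharp decoy PWMs, for differential-enrichment ranking tests."""
    rng = np.random.default_rng(seed)
    motifs = []
    for i in range(n_decoys):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        probs = np.full((L, 4), 0.01)
        cons = rng.integers(0, 4, size=L)
        probs[np.arange(L), cons] = 0.97
        motifs.append(MotifMatrix(name=f"decoy{i:03d}", probs=probs / probs.sum(1, keepdims=True),
                                  tf_family="decoy"))
    return motifs


def plant_motif_instances(
    genome: GenomeAssembly,
    truth: list[TruthPeak],
    motif: MotifMatrix,
    config: SimulationConfig,
) -> tuple[GenomeAssembly, list[tuple[str, int, str]]]:
    """Write the motif consensus into barrier-deficient peaks.

    Each BarrierDeficient peak receives one consensus instance with
    probability ``motif_plant_rate``, at a uniform offset, on a random
    strand. Returns the modified assembly and the planted positions;
    ``motif_planted`` flags on the truth peaks are updated in place.
    """
    config.validate()
    consensus = motif.consensus
    if len(consensus) > config.peak_width:
        raise ValueError("motif longer than peak width")
    rng = _sub_seed(config.seed, "motif_plant")
    seqs = {c: bytearray(s.encode()) for c, s in genome.sequence.items()}
    log: list[tuple[str, int, str]] = []
    for peak in truth:
        if peak.class_label != "BarrierDeficient":
            continue
        if rng.random() >= config.motif_plant_rate:
            continue
        iv = peak.interval
        offset = int(rng.integers(0, len(iv) - len(consensus) + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = consensus if strand == "+" else reverse_complement(consensus)
        pos = iv.start + offset
        seqs[iv.chrom][pos : pos + len(inserted)] = inserted.encode()
        peak.motif_planted = True
        log.append((iv.chrom, pos, strand))
    new_sequence = {c: bytes(b).decode() for c, b in seqs.items()}
    return GenomeAssembly(dict(genome.chrom_sizes), sequence=new_sequence), log


TRAITS = (
    "atopic dermatitis",
    "asthma",
    "allergic rhinitis",
    "total serum IgE",
    "eosinophilic esophagitis",
)


def simulate_haplotypes(
    config: SimulationConfig,
    truth: list[TruthPeak] | None = None,
) -> tuple[HaplotypePanel, pd.DataFrame, pd.DataFrame]:
    """LD-block haplotype panel plus a disease-SNP catalog.

    SNPs come in ``n_blocks`` independent blocks. Within a block each
    haplotype copies the block founder allele with probability
    ``block_copy_prob`` (else an independent draw at the block MAF), so
    expected pairwise r^2 rises with the copy probability. Each block
    designates one *peak SNP* and one *disease SNP*; in the first
    ``ld_planted_blocks`` blocks both copy the founder exactly (true
    r^2 = 1) and, when ``truth`` is given, the peak SNP sits inside a
    BarrierDeficient truth peak while the disease SNP sits outside all
    peaks. Later blocks place their peak SNP inside Decoy truth peaks
    (no LD with any disease SNP, which lives in its own block only for
    planted ones).

    Returns (panel, disease catalog, truth pair table with true r^2).
    """
    config.validate()
    rng = _sub_seed(config.seed, "haplotypes")
    H, B, S = config.n_haplotypes, config.n_blocks, config.snps_per_block
    lo, hi = config.maf_range
    c = config.block_copy_prob

    bd_peaks = [t.interval for t in truth if t.class_label == "BarrierDeficient"] if truth else []
    decoy_peaks = [t.interval for t in truth if t.class_label == "Decoy"] if truth else []
    peak_intervals = [t.interval for t in truth] if truth else []

    # genome geometry for positions (positions need not hit real sequence)
    chrom = "chr1"
    span = 400_000 if truth is None else None

    records = []
    columns = []
    catalog_rows = []
    pair_rows = []
    snp_counter = 0
    block_positions_used: set[int] = set()

    def free_position(rng, lo_pos, hi_pos):
        for _ in range(1000):
            pos = int(rng.integers(lo_pos, hi_pos))
            if pos in block_positions_used:
                continue
            if truth is not None and any(
                iv.start <= pos < iv.end for iv in peak_intervals if iv.chrom == chrom
            ):
                continue
            block_positions_used.add(pos)
            return pos
        raise RuntimeError("could not find a free SNP position")

    def in_peak_position(rng, iv):
        for _ in range(1000):
            pos = int(rng.integers(iv.start, iv.end))
            if pos not in block_positions_used:
                block_positions_used.add(pos)
                return pos
        raise RuntimeError("could not place SNP in peak")

    n_planted = min(config.ld_planted_blocks, len(bd_peaks)) if truth else config.ld_planted_blocks
    for b in range(B):
        maf = float(rng.uniform(lo, hi))
        founder = (rng.random(H) < maf).astype(np.uint8)
        # guarantee polymorphic founder
        while founder.min() == founder.max():
            founder = (rng.random(H) < maf).astype(np.uint8)
        planted = b < n_planted
        block_cols = []
        roles = ["peak", "disease"] + ["filler"] * (S - 2)
        for role in roles:
            if role in ("peak", "disease") and planted:
                col = founder.copy()  # exact copy -> true r^2 = 1 with partner
            elif role == "peak":
                # unplanted designated pair is independent (true r^2 = 0),
                # so decoy-hosted SNPs never reach the LD threshold
                col = (rng.random(H) < maf).astype(np.uint8)
                while col.min() == col.max():
                    col = (rng.random(H) < maf).astype(np.uint8)
            else:
                copy_mask = rng.random(H) < c
                independent = (rng.random(H) < maf).astype(np.uint8)
                col = np.where(copy_mask, founder, independent).astype(np.uint8)
                while col.min() == col.max():
                    independent = (rng.random(H) < maf).astype(np.uint8)
                    copy_mask = rng.random(H) < c
                    col = np.where(copy_mask, founder, independent).astype(np.uint8)
            rsid = f"rs{900000 + snp_counter}"
            # position assignment
            if truth is not None:
                if role == "peak" and planted:
                    iv = bd_peaks[b]
                    pos, pos_chrom = in_peak_position(rng, iv), iv.chrom
                elif role == "peak" and not planted and (b - n_planted) < len(decoy_peaks):
                    iv = decoy_peaks[b - n_planted]
                    pos, pos_chrom = in_peak_position(rng, iv), iv.chrom
                else:
                    pos_chrom = chrom
                    pos = free_position(rng, 0, 400_000)
            else:
                pos_chrom = chrom
                pos = free_position(rng, 0, span)
            ref, alt = "A", "G"
            records.append((rsid, pos_chrom, pos, ref, alt))
            columns.append(col)
            if role == "disease":
                catalog_rows.append(
                    {
                        "rsid": rsid,
                        "chrom": pos_chrom,
                        "pos": pos,
                        "trait": TRAITS[b % len(TRAITS)],
                        "source": "synthetic-gwas",
                    }
                )
            if role in ("peak", "disease"):
                pair_rows.append(
                    {"block": b, "role": role, "rsid": rsid,
                     "true_r2": 1.0 if planted else 0.0, "planted": planted}
                )
            snp_counter += 1
    snps = pd.DataFrame(records, columns=["rsid", "chrom", "pos", "ref", "alt"])
    panel = HaplotypePanel(
        haplotype_ids=[f"hap{i:04d}" for i in range(H)],
        snps=snps,
        alleles=np.stack(columns, axis=1),
    )
    catalog = pd.DataFrame(catalog_rows, columns=["rsid", "chrom", "pos", "trait", "source"])
    pairs = pd.DataFrame(pair_rows)
    return panel, catalog, pairs


def make_gene_models(
    genome: GenomeAssembly,
    truth: list[TruthPeak],
    config: SimulationConfig,
    condition: str = "ESS",
) -> tuple[list[GeneModel], list[GeneModel]]:
    """Gene models for TSS-profile tests.

    Returns (accessible, inaccessible): genes whose TSS sits at the
    center of a peak open in ``condition``, and control genes placed in
    inter-peak gaps (emulating expressed vs not-expressed gene lists).
    """
    rng = _sub_seed(config.seed, "genes", condition)
    accessible: list[GeneModel] = []
    open_peaks = [t for t in truth if t.presence.get(condition, False)]
    for i, t in enumerate(open_peaks):
        iv = t.interval
        strand = "+" if rng.random() < 0.5 else "-"
        tss = iv.center
        body_start = max(0, tss - 1000) if strand == "+" else max(0, tss - 3000)
        body_end = min(genome.chrom_sizes[iv.chrom], body_start + 4000)
        accessible.append(
            GeneModel(f"geneA{i:04d}", iv.chrom, tss, strand,
                      GenomicInterval(iv.chrom, body_start, body_end))
        )
    # control genes: midpoints of gaps between consecutive truth peaks
    inaccessible: list[GeneModel] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for t in truth:
        by_chrom.setdefault(t.interval.chrom, []).append(t.interval)
    i = 0
    for chrom, ivs in sorted(by_chrom.items()):
        ivs = sorted(ivs, key=lambda v: v.start)
        for a, b in zip(ivs, ivs[1:]):
            gap_mid = (a.end + b.start) // 2
            if b.start - a.end < 2000:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            body_start = max(0, gap_mid - 500)
            body_end = min(genome.chrom_sizes[chrom], gap_mid + 3500)
            inaccessible.append(
                GeneModel(f"geneB{i:04d}", chrom, gap_mid, strand,
                          GenomicInterval(chrom, body_start, body_end))
            )
            i += 1
    return accessible, inaccessible


def truth_peak_sets(truth: list[TruthPeak]):
    """Noise-free per-condition peak sets from truth presence maps.

    Returns (condition_sets, decoy_sets) as {label: [intervals]} /
    list of (label, [intervals]).
    """
    condition_sets = {c: [] for c in CONDITIONS}
    decoy_sets = {d: [] for d in DECOY_CONDITIONS}
    for t in truth:
        for c in CONDITIONS:
            if t.presence.get(c, False):
                condition_sets[c].append(t.interval)
        for d in DECOY_CONDITIONS:
            if t.presence.get(d, False):
                decoy_sets[d].append(t.interval)
    return condition_sets, decoy_sets
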