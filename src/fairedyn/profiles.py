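"""Genome-binned cross-sample correlation and TSS-centered signal profiles."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, GenomicInterval, SignalTrack


def bin_signal(track: SignalTrack, chrom_sizes: dict[str, int], bin_size: int) -> np.ndarray:
    """Mean signal per genome bin (zeros included), chromosomes in sorted
    order, last bin per chromosome possibly short."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    means = []
    for chrom in sorted(chrom_sizes):
        L = chrom_sizes[chrom]
        arr = track.data.get(chrom)
        if arr is None:
            arr = np.zeros(L)
        edges = np.arange(0, L + bin_size, bin_size)
        edges[-1] = min(edges[-1], L)
        if edges[-1] != L:
            edges = np.append(edges, L)
        cs = np.concatenate([[0.0], np.cumsum(arr)])
        sums = cs[edges[1:]] - cs[edges[:-1]]
        widths = np.diff(edges)
        means.append(sums / widths)
    return np.concatenate(means)


def genome_bins(chrom_sizes: dict[str, int], bin_size: int) -> list[GenomicInterval]:
    bins = []
    for chrom in sorted(chrom_sizes):
        L = chrom_sizes[chrom]
        for start in range(0, L, bin_size):
            bins.append(GenomicInterval(chrom, start, min(start + bin_size, L)))
    return bins


def correlation_matrix(
    tracks: list[SignalTrack],
    chrom_sizes: dict[str, int],
    bin_size: int = 10_000,
    method: str = "pearson",
    drop_all_zero_bins: bool = True,
) -> pd.DataFrame:
    """Pairwise correlation of genome-binned signal across samples.

    Bins where every track is zero are dropped by default so shared
    empty regions do not inflate the correlation. A track constant over
    the retained bins has undefined correlations, reported as NaN with
    a warning (its diagonal entry stays 1).
    """
    if len(tracks) < 2:
        raise ValueError("need at least 2 tracks")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    labels = [t.sample or f"track{i}" for i, t in enumerate(tracks)]
    binned = np.vstack([bin_signal(t, chrom_sizes, bin_size) for t in tracks])
    if drop_all_zero_bins:
        keep = (binned != 0).any(axis=0)
        binned = binned[:, keep]
    n = len(tracks)
    out = np.eye(n)
    constant = [np.ptp(binned[i]) == 0 for i in range(n)]
    if any(constant):
        warnings.warn(
            f"constant track(s) over retained bins: "
            f"{[labels[i] for i in range(n) if constant[i]]}; correlations undefined"
        )
    for i in range(n):
        for j in range(i + 1, n):
            if constant[i] or constant[j]:
                r = np.nan
            elif method == "pearson":
                r = float(np.corrcoef(binned[i], binned[j])[0, 1])
            else:
                r = float(stats.spearmanr(binned[i], binned[j]).statistic)
            out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=labels, columns=labels)


@dataclass
class TssProfile:
    """Strand-oriented mean signal around transcription start sites."""

    label: str
    flank: int
    bin_size: int
    values: np.ndarray  # length 2*flank/bin_size, 5'->3' of the gene
    n_genes: int
    n_clipped: int  # genes whose window ran off a chromosome end (zero-padded)

    @property
    def offsets(self) -> np.ndarray:
        """Bin-center offsets relative to the TSS, in bp."""
        starts = np.arange(-self.flank, self.flank, self.bin_size)
        return starts + self.bin_size / 2


def tss_profile(
    track: SignalTrack,
    genes: list[GeneModel],
    flank: int = 2500,
    bin_size: int = 50,
    label: str = "",
) -> TssProfile:
    """Average signal on [TSS - flank, TSS + flank), oriented 5'->3'.

    Minus-strand windows are reversed before binning; windows exceeding
    chromosome bounds are zero-padded and counted in ``n_clipped``.
    """
    if not genes:
        raise ValueError("empty gene list")
    if 2 * flank % bin_size != 0:
        raise ValueError("2*flank must be divisible by bin_size")
    n_bins = 2 * flank // bin_size
    acc = np.zeros(n_bins)
    n_clipped = 0
    for gene in genes:
        window = track.values(gene.chrom, gene.tss - flank, gene.tss + flank)
        chrom_len = len(track.data[gene.chrom]) if gene.chrom in track.data else 0
        if gene.tss - flank < 0 or gene.tss + flank > chrom_len:
            n_clipped += 1
        if gene.strand == "-":
            window = window[::-1]
        acc += window.reshape(n_bins, bin_size).mean(axis=1)
    return TssProfile(
        label=label or track.sample,
        flank=flank,
        bin_size=bin_size,
        values=acc / len(genes),
        n_genes=len(genes),
        n_clipped=n_clipped,
    )
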