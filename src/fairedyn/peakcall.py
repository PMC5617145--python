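"""Fragment merging, assembly filtering, coverage, and fixed-width peak
calling with a Poisson tag-density FDR.

The caller follows the fixed-width parameterization used for FAIRE data
(peak size 200 bp, at most 1 tag per base position, FDR 0.05, no local
filtering): fragment 5' starts are capped per position, counted in
sliding windows at single-base step, thresholded against a genome-wide
Poisson null at the empirical FDR, and accepted greedily in descending
count order with overlapping windows skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GenomeAssembly, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class FragmentSet:
    """Fragments from one sample, optionally tagged by source assembly."""

    sample: str
    fragments: list[GenomicInterval]
    source_tags: list[str] | None = None

    def __post_init__(self) -> None:
        if self.source_tags is not None and len(self.source_tags) != len(self.fragments):
            raise ValueError("source_tags length differs from fragments")

    def __len__(self) -> int:
        return len(self.fragments)


@dataclass
class PeakCallParams:
    peak_size: int = 200
    tbp_cap: int = 1
    fdr: float = 0.05
    local_filtering: bool = False  # retained for interface parity; always off

    def __post_init__(self) -> None:
        if self.peak_size < 1:
            raise ValueError("peak_size must be >= 1")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if self.tbp_cap < 1:
            raise ValueError("tbp_cap must be >= 1")


@dataclass
class PeakSet:
    """A labeled collection of peaks for one sample or condition."""

    label: str
    peaks: list[GenomicInterval]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.peaks)


def merge_fragment_sets(sets: list[FragmentSet]) -> FragmentSet:
    """Concatenate replicate fragment sets sharing one sample label."""
    if not sets:
        raise ValueError("no fragment sets to merge")
    labels = {s.sample for s in sets}
    if len(labels) != 1:
        raise ValueError(f"cannot merge sets with mixed sample labels: {sorted(labels)}")
    fragments = [f for s in sets for f in s.fragments]
    if all(s.source_tags is not None for s in sets):
        tags = [t for s in sets for t in s.source_tags]
    else:
        tags = None
    return FragmentSet(sample=sets[0].sample, fragments=fragments, source_tags=tags)


def filter_to_assembly(fragment_set: FragmentSet, target: str) -> FragmentSet:
    """Keep only fragments whose source tag matches the target assembly."""
    if fragment_set.source_tags is None:
        raise ValueError(
            "fragments carry no source tags; skip assembly filtering for this sample"
        )
    keep = [i for i, t in enumerate(fragment_set.source_tags) if t == target]
    removed = len(fragment_set) - len(keep)
    logger.info("filter_to_assembly(%s): removed %d of %d fragments",
                fragment_set.sample, removed, len(fragment_set))
    if not keep:
        logger.warning("no fragments tagged %r in sample %s", target, fragment_set.sample)
    return FragmentSet(
        sample=fragment_set.sample,
        fragments=[fragment_set.fragments[i] for i in keep],
        source_tags=[target] * len(keep),
    )


def coverage_track(
    fragment_set: FragmentSet,
    chrom_sizes: dict[str, int],
    normalize: bool = False,
):
    """Per-base fragment overlap count, optionally fragments-per-million."""
    from .core import SignalTrack

    diffs = {c: np.zeros(n + 1) for c, n in chrom_sizes.items()}
    for f in fragment_set.fragments:
        if f.chrom not in diffs:
            raise ValueError(f"fragment on unknown chromosome {f.chrom}")
        diffs[f.chrom][f.start] += 1
        diffs[f.chrom][min(f.end, chrom_sizes[f.chrom])] -= 1
    data = {c: np.cumsum(d[:-1]) for c, d in diffs.items()}
    n_frag = len(fragment_set)
    if normalize and n_frag > 0:
        scale = 1e6 / n_frag
        data = {c: v * scale for c, v in data.items()}
    return SignalTrack(data, sample=fragment_set.sample,
                       total_fragments=n_frag, normalized=normalize)


def _capped_tag_counts(
    fragment_set: FragmentSet, chrom_sizes: dict[str, int], tbp_cap: int
) -> tuple[dict[str, np.ndarray], int]:
    """Per-position tag counts after duplicate capping.

    The cap is applied per identical (chrom, start) position — at most
    ``tbp_cap`` fragments may share a start, the rest are treated as
    amplification duplicates and dropped. Retained fragments are then
    counted at their midpoint (the tag centered by half the fragment
    length), so window counts line up with the accessible region rather
    than trailing upstream of it by half a fragment.
    """
    counts = {c: np.zeros(n, dtype=np.int64) for c, n in chrom_sizes.items()}
    start_seen: dict[tuple[str, int], int] = {}
    total = 0
    for f in fragment_set.fragments:
        if f.chrom not in counts:
            raise ValueError(f"fragment on unknown chromosome {f.chrom}")
        key = (f.chrom, f.start)
        n_at_start = start_seen.get(key, 0)
        if n_at_start >= tbp_cap:
            continue
        start_seen[key] = n_at_start + 1
        mid = min(f.center, chrom_sizes[f.chrom] - 1)
        counts[f.chrom][mid] += 1
        total += 1
    return counts, total


def call_peaks(
    fragment_set: FragmentSet,
    chrom_sizes: dict[str, int],
    params: PeakCallParams = PeakCallParams(),
    assembly: GenomeAssembly | None = None,
) -> PeakSet:
    """Call non-overlapping fixed-width peaks at the target FDR.

    Tags are duplicate-capped per start position, placed at fragment
    midpoints, and counted in sliding windows of ``peak_size`` at
    single-base step. Null model: window counts ~ Poisson(lambda) with
    lambda = N_capped * peak_size / effective genome length (total
    length minus N runs when the assembly sequence is available). The
    count threshold m is the smallest integer at which the expected
    number of null windows at or above m, divided by the observed
    number, is at most the FDR. Windows are then accepted greedily in
    descending count order (ties to the leftmost coordinate), skipping
    windows overlapping an accepted peak.
    """
    if len(fragment_set) == 0:
        raise ValueError("cannot call peaks on an empty fragment set")
    w = params.peak_size
    starts, n_capped = _capped_tag_counts(fragment_set, chrom_sizes, params.tbp_cap)
    effective = assembly.effective_length() if assembly is not None else sum(chrom_sizes.values())
    lam = n_capped * w / effective
    if lam <= 0:
        raise ValueError("null rate lambda is zero; no usable fragments")

    window_counts: dict[str, np.ndarray] = {}
    n_windows = 0
    for chrom, arr in starts.items():
        if len(arr) < w:
            continue
        cs = np.concatenate([[0], np.cumsum(arr)])
        wc = cs[w:] - cs[:-w]  # count of starts in [i, i+w)
        window_counts[chrom] = wc
        n_windows += len(wc)
    if n_windows == 0:
        return PeakSet(label=fragment_set.sample, peaks=[], provenance="call_peaks")

    max_count = max(int(wc.max()) for wc in window_counts.values())
    # observed windows with count >= m, for every m
    obs_ge = np.zeros(max_count + 2, dtype=np.int64)
    for wc in window_counts.values():
        binc = np.bincount(wc, minlength=max_count + 1)
        obs_ge[: max_count + 1] += binc[::-1].cumsum()[::-1]
    threshold = None
    for m in range(1, max_count + 1):
        if obs_ge[m] == 0:
            break
        expected = n_windows * stats.poisson.sf(m - 1, lam)
        if expected / obs_ge[m] <= params.fdr:
            threshold = m
            break
    logger.info("call_peaks(%s): N_capped=%d lambda=%.4f threshold=%s",
                fragment_set.sample, n_capped, lam, threshold)
    if threshold is None:
        return PeakSet(label=fragment_set.sample, peaks=[], provenance="call_peaks")

    candidates = []
    for chrom in sorted(window_counts):
        wc = window_counts[chrom]
        for pos in np.flatnonzero(wc >= threshold):
            candidates.append((-int(wc[pos]), chrom, int(pos)))
    candidates.sort()

    blocked = {c: np.zeros(len(wc), dtype=bool) for c, wc in window_counts.items()}
    peaks: list[GenomicInterval] = []
    for neg_count, chrom, pos in candidates:
        if blocked[chrom][pos]:
            continue
        peaks.append(GenomicInterval(chrom, pos, pos + w,
                                     name=f"peak{len(peaks) + 1}", score=float(-neg_count)))
        lo = max(0, pos - w + 1)
        hi = min(len(blocked[chrom]), pos + w)
        blocked[chrom][lo:hi] = True
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return PeakSet(label=fragment_set.sample, peaks=peaks,
                   provenance=f"call_peaks(size={w}, tbp={params.tbp_cap}, fdr={params.fdr})")
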