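"""Independent brute-force oracles used to validate the implementations.

These deliberately use naive explicit-loop constructions (bisect window
counting, quadratic classification, 2x2 contingency r^2) so they share
no code path with the package.
"""

from bisect import bisect_left
from collections import Counter

from scipy import stats

from fairedyn.core import GenomicInterval


def oracle_call_peaks(fragments, chrom_sizes, peak_size, tbp_cap, fdr, effective_length):
    """Literal window-enumeration peak calling.

    Cap fragments per identical (chrom, start); place each retained tag
    at the fragment midpoint; enumerate every window at single-base
    step counting tags by bisection; threshold against the Poisson
    null; greedy non-overlapping acceptance in descending count order,
    ties leftmost.
    """
    seen = Counter()
    tags = {c: [] for c in chrom_sizes}
    n_tags = 0
    for f in fragments:
        if seen[(f.chrom, f.start)] >= tbp_cap:
            continue
        seen[(f.chrom, f.start)] += 1
        mid = min((f.start + f.end) // 2, chrom_sizes[f.chrom] - 1)
        tags[f.chrom].append(mid)
        n_tags += 1
    for c in tags:
        tags[c].sort()
    lam = n_tags * peak_size / effective_length
    windows = []
    for chrom in sorted(chrom_sizes):
        L = chrom_sizes[chrom]
        for pos in range(L - peak_size + 1):
            count = bisect_left(tags[chrom], pos + peak_size) - bisect_left(tags[chrom], pos)
            windows.append((chrom, pos, count))
    if not windows:
        return []
    max_count = max(w[2] for w in windows)
    threshold = None
    for m in range(1, max_count + 1):
        observed = sum(1 for w in windows if w[2] >= m)
        if observed == 0:
            break
        expected = len(windows) * stats.poisson.sf(m - 1, lam)
        if expected / observed <= fdr:
            threshold = m
            break
    if threshold is None:
        return []
    candidates = sorted(
        (w for w in windows if w[2] >= threshold),
        key=lambda w: (-w[2], w[0], w[1]),
    )
    accepted = []
    for chrom, pos, count in candidates:
        clash = any(
            c == chrom and pos < p + peak_size and p < pos + peak_size
            for c, p, _ in accepted
        )
        if not clash:
            accepted.append((chrom, pos, count))
    accepted.sort(key=lambda w: (w[0], w[1]))
    return [
        GenomicInterval(c, p, p + peak_size, score=float(n)) for c, p, n in accepted
    ]


def oracle_overlap_fraction(a, b):
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    return max(ov, 0) / (a.end - a.start)


def oracle_classify(candidates, condition_peaks, decoy_peaks, rules):
    """Quadratic double-loop application of the presence/absence rules."""
    out = []
    for iv in candidates:
        assigned = "Unclassified"
        for rule in rules:
            ok = True
            for label in rule.require_present:
                best = max(
                    (oracle_overlap_fraction(iv, other) for other in condition_peaks[label]),
                    default=0.0,
                )
                if best < rule.presence_fraction:
                    ok = False
                    break
            if ok:
                for label in rule.require_absent:
                    best = max(
                        (oracle_overlap_fraction(iv, other) for other in condition_peaks[label]),
                        default=0.0,
                    )
                    if best >= rule.absence_fraction:
                        ok = False
                        break
            if ok and rule.decoy_filter == "exclude_any":
                for peaks in decoy_peaks:
                    best = max(
                        (oracle_overlap_fraction(iv, other) for other in peaks), default=0.0
                    )
                    if best >= rule.absence_fraction:
                        ok = False
                        break
            if ok and rule.decoy_filter == "require_at_least_k":
                n_hit = sum(
                    max((oracle_overlap_fraction(iv, other) for other in peaks), default=0.0)
                    >= rule.presence_fraction
                    for peaks in decoy_peaks
                )
                ok = n_hit >= rule.k
            if ok:
                assigned = rule.class_name
                break
        out.append(assigned)
    return out


def oracle_r_squared(col_a, col_b):
    """r^2 from the explicit 2x2 haplotype contingency table."""
    n = len(col_a)
    n11 = sum(1 for a, b in zip(col_a, col_b) if a == 1 and b == 1)
    n10 = sum(1 for a, b in zip(col_a, col_b) if a == 1 and b == 0)
    n01 = sum(1 for a, b in zip(col_a, col_b) if a == 0 and b == 1)
    p_a = (n11 + n10) / n
    p_b = (n11 + n01) / n
    d = n11 / n - p_a * p_b
    return d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))


def oracle_binomial_tail(n, k, p):
    """Exact upper-tail binomial by direct summation."""
    from math import comb

    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))
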