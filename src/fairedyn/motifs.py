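"""PWM scanning and differential motif enrichment.

Foreground peak sequences are scanned whole (not just peak centers)
against a motif library; the background is the union of the two peak
sets under comparison, dinucleotide-shuffled (Altschul-Erickson Eulerian
construction) so base composition and CpG-like neighbor effects are
preserved. Per-motif enrichment is an upper-tail binomial on the count
of foreground sequences with at least one hit, against the
Laplace-smoothed background hit rate.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenomeAssembly, merge_intervals

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NEG_INF = -1e30


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifMatrix:
    """A position frequency matrix with a log-odds scoring view.

    ``probs`` is L x 4 over ACGT, column-stochastic per position.
    Pseudocount smoothing is applied when scoring, so zero entries never
    produce infinite log-odds.
    """

    name: str
    probs: np.ndarray
    tf_family: str | None = None
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError(f"motif {self.name}: probs must be Lx4")
        if self.probs.shape[0] < 1:
            raise ValueError(f"motif {self.name}: empty matrix")
        if (self.probs < 0).any():
            raise ValueError(f"motif {self.name}: negative probability")
        sums = self.probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"motif {self.name}: positions must sum to 1")

    def __len__(self) -> int:
        return self.probs.shape[0]

    @property
    def smoothed_probs(self) -> np.ndarray:
        p = self.probs + self.pseudocount
        return p / p.sum(axis=1, keepdims=True)

    @property
    def log_odds(self) -> np.ndarray:
        """L x 5 natural-log odds; column 4 (N) scores effectively -inf."""
        lo = np.log(self.smoothed_probs / self.background[None, :])
        return np.hstack([lo, np.full((len(self), 1), _NEG_INF)])

    @property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=1))


def encode_sequence(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-ACGTN base {exc.args[0]!r} in sequence") from exc


# ---------------------------------------------------------------------------
# Dinucleotide-preserving shuffle (Altschul-Erickson)


def _shuffle_segment(seq: str, rng: np.random.Generator) -> str:
    """Uniform shuffle preserving all 16 dinucleotide counts.

    Random-arborescence Eulerian construction: pick a random last exit
    edge per vertex, accept when those edges form paths into the final
    vertex, shuffle the remaining edges, and walk.
    """
    if len(seq) < 3 or len(set(seq)) == 1:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last_vertex = seq[-1]
    vertices = [v for v in edges if v != last_vertex]
    for _ in range(10_000):
        last_edges = {v: edges[v][rng.integers(len(edges[v]))] for v in vertices}
        # each vertex must reach last_vertex by following last edges
        ok = True
        for v in vertices:
            seen = {v}
            cur = v
            while cur != last_vertex:
                cur = last_edges.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("failed to sample a connected arborescence")
    new_edges: dict[str, list[str]] = {}
    for v, succ in edges.items():
        rest = list(succ)
        if v in last_edges:
            rest.remove(last_edges[v])
        rng.shuffle(rest)
        if v in last_edges:
            rest.append(last_edges[v])
        new_edges[v] = rest
    out = [seq[0]]
    counters = {v: 0 for v in new_edges}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = new_edges[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def dinucleotide_shuffle(seq: str, seed: int) -> str:
    """Shuffle ``seq`` preserving its dinucleotide count multiset.

    First/last characters are preserved; N runs act as segment breaks and
    are left in place, each flanked segment shuffled independently.
    Deterministic under ``seed``.
    """
    if len(seq) < 2:
        warnings.warn("sequence shorter than 2 bases returned unchanged")
        return seq
    rng = np.random.default_rng(seed)
    seq = seq.upper()
    out: list[str] = []
    i = 0
    while i < len(seq):
        if seq[i] == "N":
            j = i
            while j < len(seq) and seq[j] == "N":
                j += 1
            out.append("N" * (j - i))
            i = j
        else:
            j = i
            while j < len(seq) and seq[j] != "N":
                j += 1
            out.append(_shuffle_segment(seq[i:j], rng))
            i = j
    return "".join(out)


def dinucleotide_counts(seq: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for a, b in zip(seq, seq[1:]):
        counts[a + b] = counts.get(a + b, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Sequence extraction and backgrounds


def extract_peak_sequences(peaks, genome: GenomeAssembly) -> list[str]:
    """Full-span forward-strand sequence for every peak interval."""
    return [genome.fetch(iv.chrom, iv.start, iv.end) for iv in peaks]


def build_background(set_a, set_b, genome: GenomeAssembly, seed: int) -> list[str]:
    """Dinucleotide-shuffled sequences of the merged union of two peak sets.

    One background serves both directions of the A-vs-B comparison.
    Per-sequence seeds are derived from ``seed`` so the result is stable
    under reordering of the input sets.
    """
    union = merge_intervals(list(set_a) + list(set_b))
    if not union:
        raise ValueError("empty union of peak sets")
    seqs = extract_peak_sequences(union, genome)
    out = []
    for iv, seq in zip(union, seqs):
        sub = zlib.crc32(f"{iv.chrom}:{iv.start}-{iv.end}".encode()) & 0x7FFFFFFF
        out.append(dinucleotide_shuffle(seq, seed=(seed * 2654435761 + sub) % (2**31)))
    return out


# ---------------------------------------------------------------------------
# Scanning and enrichment


def scan_motif(seq: str, motif: MotifMatrix, threshold_frac: float = 0.8):
    """Log-odds scan of both strands; hits where score >= frac * max score.

    Returns (position, strand, score) triples, positions 0-based on the
    forward sequence. Windows containing N never score above threshold.
    """
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must be in (0, 1]")
    L = len(motif)
    if L > len(seq):
        return []
    lo = motif.log_odds
    enc = encode_sequence(seq)
    windows = np.lib.stride_tricks.sliding_window_view(enc, L)
    fwd = lo[np.arange(L)[None, :], windows].sum(axis=1)
    # reverse strand: score of revcomp(motif) on forward sequence
    lo_rc = lo[::-1, [3, 2, 1, 0, 4]]
    rev = lo_rc[np.arange(L)[None, :], windows].sum(axis=1)
    threshold = threshold_frac * motif.max_score
    hits = []
    for pos in np.flatnonzero(fwd >= threshold):
        hits.append((int(pos), "+", float(fwd[pos])))
    for pos in np.flatnonzero(rev >= threshold):
        hits.append((int(pos), "-", float(rev[pos])))
    return sorted(hits)


def _hit_count(seqs, motif: MotifMatrix, threshold_frac: float) -> int:
    """Number of sequences with at least one hit."""
    n = 0
    for seq in seqs:
        if scan_motif(seq, motif, threshold_frac):
            n += 1
    return n


def binomial_enrichment_pvalue(fg_hits: int, fg_n: int, bg_hits: int, bg_n: int) -> float:
    """Upper-tail binomial P[X >= fg_hits] at the smoothed background rate.

    The background rate is Laplace-smoothed, (bg_hits+1)/(bg_n+2), so a
    hit-free background cannot produce a degenerate zero rate.
    """
    p_hat = (bg_hits + 1) / (bg_n + 2)
    p = float(stats.binom.sf(fg_hits - 1, fg_n, p_hat))
    return max(p, 1e-300)


def hypergeometric_enrichment_pvalue(fg_hits: int, fg_n: int, bg_hits: int, bg_n: int) -> float:
    total = fg_n + bg_n
    p = float(stats.hypergeom.sf(fg_hits - 1, total, fg_hits + bg_hits, fg_n))
    return max(p, 1e-300)


ENRICHMENT_COLUMNS = [
    "motif", "tf_family", "fg_n", "fg_hits", "bg_n", "bg_hits",
    "p_value", "neg_log10_p",
]


def motif_enrichment(
    fg_seqs,
    bg_seqs,
    motifs,
    threshold_frac: float = 0.8,
    method: str = "binomial",
) -> pd.DataFrame:
    """Per-motif enrichment of foreground over background sequences.

    Rows sorted by descending -log10 p.
    """
    if not fg_seqs or not bg_seqs:
        raise ValueError("foreground and background must be non-empty")
    if method == "binomial":
        pfun = binomial_enrichment_pvalue
    elif method == "hypergeometric":
        pfun = hypergeometric_enrichment_pvalue
    else:
        raise ValueError(f"unknown enrichment method {method!r}")
    rows = []
    for motif in motifs:
        fg_hits = _hit_count(fg_seqs, motif, threshold_frac)
        bg_hits = _hit_count(bg_seqs, motif, threshold_frac)
        p = pfun(fg_hits, len(fg_seqs), bg_hits, len(bg_seqs))
        rows.append(
            {
                "motif": motif.name,
                "tf_family": motif.tf_family,
                "fg_n": len(fg_seqs),
                "fg_hits": fg_hits,
                "bg_n": len(bg_seqs),
                "bg_hits": bg_hits,
                "p_value": p,
                "neg_log10_p": -np.log10(p),
            }
        )
    df = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS)
    return df.sort_values("neg_log10_p", ascending=False, kind="stable").reset_index(drop=True)


def pairwise_motif_table(enrich_a: pd.DataFrame, enrich_b: pd.DataFrame) -> pd.DataFrame:
    """Join two enrichment tables for a two-condition comparison scatter.

    delta = (-log10 pA) - (-log10 pB) ranks motifs by differential
    enrichment between the two conditions.
    """
    if set(enrich_a["motif"]) != set(enrich_b["motif"]):
        raise ValueError("motif libraries differ between the two enrichment tables")
    a = enrich_a.set_index("motif")
    b = enrich_b.set_index("motif")
    out = pd.DataFrame(
        {
            "motif": a.index,
            "tf_family": a["tf_family"].values,
            "neg_log10_p_a": a["neg_log10_p"].values,
            "neg_log10_p_b": b.loc[a.index, "neg_log10_p"].values,
        }
    )
    out["delta"] = out["neg_log10_p_a"] - out["neg_log10_p_b"]
    return out.sort_values("delta", ascending=False, kind="stable").reset_index(drop=True)
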