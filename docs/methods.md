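# Methods

`fairedyn` analyzes chromatin accessibility (FAIRE-style fragment data)
across experimental conditions. This note records the models, the
parameter defaults and why they hold, the numerical choices, and what
the synthetic data does and does not establish.

## Coordinate conventions

All coordinates are 0-based half-open (BED convention) everywhere in
memory. VCF positions are decremented on ingest and incremented on
output; SNP/peak intersection is start-inclusive, end-exclusive.
Identifiers (rsIDs) are the join key between the haplotype panel, the
disease catalog, and peak overlaps; positions are used only for
interval intersection.

## Peak calling

The caller produces fixed-width, non-overlapping peaks, parameterized
the way FAIRE data are commonly processed: `peak_size` 200 bp,
`tbp_cap` 1, `fdr` 0.05, local-area filtering off. The procedure:

1. **Duplicate capping.** At most `tbp_cap` fragments may share an
   identical (chrom, start) position; the excess is treated as
   amplification duplicates and dropped.
2. **Tag placement.** Each retained fragment contributes one tag at its
   midpoint. Centering tags by half the fragment length keeps window
   counts aligned with the accessible region itself; counting raw 5'
   ends would displace every call upstream by roughly half a fragment
   (75–300 bp at the 150–600 bp fragment lengths this assay produces)
   and generate spurious flanking calls from the start-density shoulder.
3. **Window counts.** Tags are counted in sliding windows of
   `peak_size` at single-base step.
4. **Poisson null.** Window counts under no enrichment are modeled as
   Poisson(λ), λ = N·w/G with N the capped tag count, w the window
   width, and G the *effective* genome length (total length minus N
   runs — a mappability stand-in; configurable).
5. **FDR threshold.** The count threshold m is the smallest integer
   with `n_windows · P(Poisson(λ) ≥ m) / #{windows ≥ m} ≤ fdr`.
   Because overlapping windows over one tag cluster all enter the
   observed count, an isolated noise cluster can occasionally clear the
   threshold; the procedure controls the *rate* of such calls at the
   FDR, not their absence.
6. **Greedy selection.** Windows with count ≥ m are accepted in
   descending count order, ties broken toward the smaller coordinate;
   any window overlapping an accepted peak is skipped. Output peaks
   have exact width `peak_size` and score = window count.

No local-background filtering is implemented (the parameterization
turns it off), and adjacent windows are never merged — fidelity by
omission. The caller is checked in the test suite against an
independent brute-force enumeration of the same definition.

## Peak classification

`overlap_fraction(a, b)` is the fraction of *a* covered by *b*
(asymmetric, like `-f` overlap semantics of the common interval tools).
Presence requires max overlap ≥ 0.25 of the query peak; exclusion
triggers at ≥ 0.10 ("at least 10%" — exactly 10% excludes). Exclusion
removes whole peaks, not trimmed sub-regions; this peak-level reading
is a deliberate choice where region-level subtraction would also be
defensible.

Two rule sets ship, applied first-match-wins in declared order (order
matters only when rules overlap; the shipped five-class set is mutually
exclusive on clean presence patterns):

| class | present (≥25%) | absent (<10%) | decoys |
|---|---|---|---|
| Epidermal | Keratinocyte, ESS | — | excluded |
| ThreeD | ESS, Graft | Keratinocyte | excluded |
| Stable | Graft, TapeStrip | ESS | excluded |
| IntactBarrier | Graft | ESS, TapeStrip | excluded |
| BarrierDeficient | ESS, TapeStrip | Graft | excluded |

The Epidermal rule leaves Graft unconstrained (its membership is
genuinely ambiguous in the class's informal definition); a strict
variant requiring Graft is available via `fig3_rules(strict_epidermal=True)`.

The TAD-scale set: Housekeeping (present in all four conditions *and*
in ≥ 3 decoy cell types at 25%), then Epidermal (all four, decoys
excluded), ThreeD (ESS+Graft+TapeStrip, not Keratinocyte), and
BarrierDeficient (ESS+TapeStrip, not Graft/Keratinocyte), all decoy-
excluded.

The candidate universe is the union of all condition peaks,
de-duplicated by exact interval identity only. Called peaks from
different conditions over one region are slightly jittered copies, so
class counts are counts of distinct called intervals, not of underlying
regions; truth-level recovery metrics map candidates back to planted
regions by overlap.

Nearest-gene annotation minimizes |peak center − TSS|, ties to the
smaller coordinate and flagged. Distances are signed by gene strand
(negative = upstream). Regulatory domains follow the basal+extension
rule: basal = 5 kb upstream / 1 kb downstream of the TSS (strand-
oriented), extended up to 1 Mb but stopping at neighboring genes' basal
domains, never shrinking below the gene's own basal window, clipped at
chromosome ends.

Gene-set enrichment is a hypergeometric upper tail over a user-supplied
universe with Benjamini–Hochberg correction; sets with fewer than 30
genes in the universe are dropped. The binomial-over-base-pairs variant
used by web tools for regulatory-domain association is *not*
reimplemented; this is a known limitation when comparing against those
tools' p-values.

## Differential motif enrichment

Sequences are whole peak spans, forward strand. The background for an
A-vs-B comparison is the merged interval union of both sets, each
sequence scrambled by an Altschul–Erickson dinucleotide-preserving
shuffle (random last-edge arborescence + Eulerian walk, uniform over
valid shuffles; endpoints fixed; N runs break sequences into
independently shuffled segments). One background serves both directions
of the comparison, and per-sequence seeds are derived from the interval
coordinates so the background is invariant to input order.

Scanning: natural-log odds of the pseudocount-smoothed PWM
(pseudocount 0.001) against a uniform base background, both strands; a
window is a hit when its score reaches `threshold_frac` (default 0.8)
of the motif's maximum attainable score. Per-motif thresholds of the
upstream motif libraries are not reproducible, so the fraction-of-max
rule is the package's own convention, configurable per scan. Windows
containing N score −∞.

Significance: with n foreground sequences of which k contain ≥ 1 hit,
and a background hit rate Laplace-smoothed as p̂ = (k_bg+1)/(n_bg+2),
the p-value is the upper binomial tail P[X ≥ k | n, p̂]. A
hypergeometric alternative is available. The plug-in p̂ makes the test
slightly anti-conservative when the background is as small as the
foreground; in the intended regime (background = scrambled union, the
larger set) the null distribution of p is near-uniform, and the test
suite checks this at background ≫ foreground. No multiple-testing
correction is applied in the pairwise table (raw −log₁₀ p is the
plotted quantity); BH is available for single-set analyses.

## LD analysis

r² is computed directly from phased haplotype columns:
D = p_AB − p_A·p_B, r² = D²/(p_A(1−p_A)p_B(1−p_B)). Unphased input is
rejected, never imputed; monomorphic SNPs are errors. Strong LD is
r² ≥ 0.8 — the threshold is stated both as "greater than 0.8" and as a
"0.8–1" band in common usage, and the inclusive reading is used.
Self-pairs (an in-peak SNP that is itself disease-associated) are
reported as tier *strong* with r² printed `NA`. The disease-SNP search
can be confined to a region (e.g. a TAD) for tractability, matching how
such analyses are usually restricted to one locus neighborhood.

## Synthetic data

The generator is a pure function of (config, seed); every stream is
derived deterministically from the global seed plus a role label, so
per-condition outputs are independent but reproducible.

- **Genome**: i.i.d. sequence, GC 0.41 (human-like), 2 chromosomes ×
  400 kb by default. Small enough that the full suite runs in seconds,
  large enough for ~210 planted peaks at the required spacing.
- **Truth peaks**: 30 per class at 400 bp, uniformly placed with gaps
  ≥ 2× the maximum fragment length so neighboring peaks cannot share
  fragments. Presence patterns follow the class table above, plus
  Housekeeping (all conditions + all 4 decoy cell types) and Decoy
  (decoy cell types only).
- **Fragments**: midpoints from a piecewise-constant Poisson intensity
  — background 0.01 fragments/bp, ×12 inside peaks present in the
  condition; lengths uniform on 150–600 bp (the fragmentation range the
  assay targets); clipped at chromosome ends. This is deliberately not
  a nucleosome-occupancy model: the pipeline consumes only interval
  coverage, so the simplest model exercising enrichment suffices.
  Graft/TapeStrip samples carry 5% mouse-tagged contaminant fragments
  (the xenograft setting), removed by `filter_to_assembly` before
  calling. Depth is a free parameter of the synthetic design; the
  defaults give ~13k fragments per replicate, chosen so single
  replicates already support peak calling.
- **Motif planting**: the AP-1-like consensus (TGACTCA) is written at a
  uniform offset, random strand, into 80% of BarrierDeficient peaks.
  Writing the consensus rather than a PWM sample maximizes
  detectability, which is the point of the recovery test.
- **Haplotypes**: 200 haplotypes, 20 independent blocks of 10 SNPs,
  MAF uniform on (0.1, 0.5). Within a block each haplotype copies the
  block founder allele with probability c = 0.9 (else an independent
  draw at the block MAF), so expected pairwise r² increases with c.
  Eight blocks plant a peak-SNP/disease-SNP pair copying the founder
  exactly (true r² = 1), the peak SNP inside a BarrierDeficient truth
  peak; unplanted designated peak SNPs are drawn independently of their
  founder (true r² = 0) and may sit inside Decoy peaks, so the LD
  report's negative space is also tested. This is a block-copying
  model, not a coalescent: it trades realism of allele-frequency
  spectra and recombination gradients for direct control of target r².

**What passing the synthetic tests shows — and does not.** The
generator reproduces the *statistical structure* the analysis relies on
(enrichment of open regions, class presence patterns, motif
concentration in one class, block LD), not the texture of real data: no
mappability/repeat structure, no GC bias, no nucleosome phasing, no
chimeric fragments, uniform fragment lengths rather than a sonication
distribution, and an i.i.d. genome. Recovery rates measured here are
therefore upper bounds on real-data performance; headline genome-wide
peak-class counts from any particular tissue experiment are not
reproducible from synthetic data and are not targeted.

## Determinism and numerics

- A single global seed derives every per-stage and per-sequence
  substream (CRC of a role label mixed into a `SeedSequence`), so
  partial reruns reproduce and outputs are byte-identical across runs.
- Greedy peak selection and nearest-gene ties break toward the smaller
  coordinate; classification applies rules in declared order.
- p-values are floored at 1e-300 to keep −log₁₀ finite; PWM rows are
  validated to sum to 1 within 1e-6 and smoothed before log-odds.
- Degenerate inputs fail loudly: empty fragment sets, λ = 0, empty
  peak-set unions, monomorphic SNPs, constant signal tracks (reported
  as missing correlations with a warning), genes lists empty, universes
  empty.

## Test design

Every nontrivial statistic is checked against an independent reference
implementation living in the test suite: a literal window-enumeration
peak caller, a quadratic double-loop classifier, a 2×2 contingency r²,
and exact binomial/hypergeometric tail summations. Property-based tests
(hypothesis) cover BED round-tripping, dinucleotide-count conservation
of the shuffle, and r² symmetry/flip invariance. `scripts/acceptance.py`
re-runs the full analysis from scratch at a caller-supplied seed and
reports the measured quantities; problem sizes there match the suite
defaults (2 × 400 kb genome, 30 peaks/class, 2 replicates, 50-motif
decoy library, 200-haplotype panel).
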