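"""Readers and writers for the text formats the pipeline touches.

BED3/BED6, bedGraph, FASTA, chrom.sizes, PFM motif libraries, GMT gene
sets, SNP-catalog TSV, and a minimal phased-GT VCF subset. All parsers
enforce the package-wide 0-based half-open convention and report
malformed lines by number. FASTA goes through Biopython and VCF through
pysam; the line-oriented formats are parsed directly so that errors can
name the offending line.
"""

from __future__ import annotations

import contextlib
import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .core import GenomeAssembly, GenomicInterval, SignalTrack
from .ld import HaplotypePanel
from .motifs import MotifMatrix

logger = logging.getLogger(__name__)

SNP_CATALOG_COLUMNS = ["rsid", "chrom", "pos", "trait", "source"]


@contextlib.contextmanager
def _open_text(source, mode: str = "r"):
    """Accept a path or an open text stream."""
    if isinstance(source, (str, Path, os.PathLike)):
        with open(source, mode) as handle:
            yield handle
    else:
        yield source


class BedParseError(ValueError):
    pass


def _is_skippable(line: str) -> bool:
    s = line.strip()
    return not s or s.startswith(("#", "track", "browser"))


def read_bed(source, assembly: GenomeAssembly | None = None) -> list[GenomicInterval]:
    """Parse BED3/BED6 into intervals, in file order.

    Track/browser/comment lines are skipped; coordinate errors raise
    :class:`BedParseError` naming the line. When ``assembly`` is given,
    intervals beyond chromosome bounds are rejected.
    """
    intervals: list[GenomicInterval] = []
    with _open_text(source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            if _is_skippable(raw):
                continue
            fields = raw.rstrip("\r\n").rstrip().split("\t")
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: expected >=3 columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise BedParseError(f"line {lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                iv = GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
            if assembly is not None:
                try:
                    assembly.check_interval(iv)
                except ValueError as exc:
                    raise BedParseError(f"line {lineno}: {exc}") from exc
            intervals.append(iv)
    return intervals


def write_bed(intervals, dest) -> None:
    with _open_text(dest, "w") as handle:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand != ".":
                fields.append(iv.name if iv.name is not None else ".")
                fields.append(f"{iv.score:g}" if iv.score is not None else ".")
                fields.append(iv.strand)
            handle.write("\t".join(fields) + "\n")


def read_bedgraph(
    source, chrom_sizes: dict[str, int] | None = None, **track_kwargs
) -> SignalTrack:
    """Parse 4-column bedGraph into a dense :class:`SignalTrack`.

    Uncovered positions read 0. Overlapping intervals on one chromosome
    are an error; abutting equal-valued runs are fine (the dense
    representation merges them by construction).
    """
    rows: dict[str, list[tuple[int, int, float]]] = {}
    with _open_text(source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            if _is_skippable(raw):
                continue
            fields = raw.rstrip("\r\n").rstrip().split("\t")
            if len(fields) < 4:
                raise BedParseError(f"line {lineno}: bedGraph needs 4 columns")
            chrom = fields[0]
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: malformed bedGraph fields") from exc
            if start < 0 or start >= end:
                raise BedParseError(f"line {lineno}: bad interval {start}-{end}")
            rows.setdefault(chrom, []).append((start, end, value))
    sizes = dict(chrom_sizes) if chrom_sizes else {}
    for chrom, recs in rows.items():
        observed_max = max(end for _, end, _ in recs)
        if chrom not in sizes:
            sizes[chrom] = observed_max
        elif observed_max > sizes[chrom]:
            raise BedParseError(f"{chrom}: interval end {observed_max} beyond chromosome size")
    data = {c: np.zeros(n) for c, n in sizes.items()}
    for chrom, recs in rows.items():
        covered = np.zeros(sizes[chrom], dtype=bool)
        for start, end, value in recs:
            if covered[start:end].any():
                raise BedParseError(f"overlapping bedGraph intervals on {chrom} at {start}-{end}")
            covered[start:end] = True
            data[chrom][start:end] = value
    return SignalTrack(data, **track_kwargs)


def write_bedgraph(track: SignalTrack, dest) -> None:
    """Run-length compress a track to bedGraph, omitting zero runs."""
    with _open_text(dest, "w") as handle:
        for chrom in sorted(track.data):
            arr = track.data[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(arr)]])
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    handle.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_fasta(source) -> GenomeAssembly:
    with _open_text(source) as handle:
        records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    if not records:
        raise ValueError("no FASTA records found")
    bad = set("".join(records.values())) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in FASTA: {sorted(bad)}")
    return GenomeAssembly({c: len(s) for c, s in records.items()}, sequence=records)


def write_fasta(assembly: GenomeAssembly, dest, width: int = 60) -> None:
    if assembly.sequence is None:
        raise ValueError("assembly has no sequence to write")
    with _open_text(dest, "w") as handle:
        for chrom in assembly.sequence:
            handle.write(f">{chrom}\n")
            seq = assembly.sequence[chrom]
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def read_chrom_sizes(source) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with _open_text(source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            if not raw.strip():
                continue
            fields = raw.split()
            if len(fields) < 2:
                raise ValueError(f"line {lineno}: chrom.sizes needs 2 columns")
            sizes[fields[0]] = int(fields[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], dest) -> None:
    with _open_text(dest, "w") as handle:
        for chrom, n in sizes.items():
            handle.write(f"{chrom}\t{n}\n")


# ---------------------------------------------------------------------------
# PFM motif libraries


def read_pfm_library(source) -> list[MotifMatrix]:
    """Parse a text PFM library: ``>name [family]`` headers followed by a
    4-row (rows = A,C,G,T) or L-row x 4-column ACGT count/probability
    matrix. Counts are normalized to column-stochastic probabilities.
    """
    motifs: list[MotifMatrix] = []
    name = family = None
    block: list[list[float]] = []

    def flush():
        nonlocal block
        if name is None:
            return
        if not block:
            raise ValueError(f"motif {name}: empty matrix")
        arr = np.array(block, dtype=float)
        if arr.shape[0] == 4 and arr.shape[1] != 4:
            arr = arr.T  # 4 rows of length L -> L x 4
        elif arr.shape == (4, 4):
            pass  # ambiguous; treat as L=4 positions x ACGT columns
        elif arr.shape[1] != 4:
            raise ValueError(
                f"motif {name}: matrix must be 4xL or Lx4 over ACGT, got {arr.shape}"
            )
        if (arr < 0).any():
            raise ValueError(f"motif {name}: negative matrix entry")
        colsums = arr.sum(axis=1)
        if (colsums == 0).any():
            raise ValueError(f"motif {name}: position with all-zero counts")
        motifs.append(MotifMatrix(name=name, probs=arr / colsums[:, None], tf_family=family))
        block = []

    row_labels = {"A": 0, "C": 1, "G": 2, "T": 3}
    with _open_text(source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                name = parts[0]
                family = parts[1].strip() if len(parts) > 1 else None
                continue
            if name is None:
                raise ValueError(f"line {lineno}: matrix data before any motif header")
            tokens = line.replace("[", " ").replace("]", " ").replace("|", " ").split()
            if tokens and tokens[0].upper() in row_labels and len(tokens) > 1:
                tokens = tokens[1:]
            try:
                block.append([float(t) for t in tokens])
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric matrix entry") from exc
        flush()
    if not motifs:
        raise ValueError("no motifs found")
    return motifs


def write_pfm_library(motifs, dest) -> None:
    with _open_text(dest, "w") as handle:
        for m in motifs:
            header = f">{m.name}"
            if m.tf_family:
                header += f" {m.tf_family}"
            handle.write(header + "\n")
            for base_idx, base in enumerate("ACGT"):
                vals = " ".join(f"{v:.6g}" for v in m.probs[:, base_idx])
                handle.write(f"{base} {vals}\n")


# ---------------------------------------------------------------------------
# GMT gene sets and SNP catalogs


def read_gmt(source) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with _open_text(source) as handle:
        for lineno, raw in enumerate(handle, start=1):
            if not raw.strip():
                continue
            fields = raw.rstrip("\r\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: GMT needs name, description, >=1 gene")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], dest) -> None:
    with _open_text(dest, "w") as handle:
        for set_name, genes in sets.items():
            handle.write("\t".join([set_name, "na"] + sorted(genes)) + "\n")


def read_snp_catalog(source) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t")
    missing = [c for c in SNP_CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SNP catalog missing columns: {missing}")
    return df[SNP_CATALOG_COLUMNS].astype({"pos": int})


def write_snp_catalog(df: pd.DataFrame, dest) -> None:
    df[SNP_CATALOG_COLUMNS].to_csv(dest, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Minimal VCF subset (phased GT only)


def read_vcf_haplotypes(source) -> HaplotypePanel:
    """Load biallelic phased SNPs from VCF into a haplotype panel.

    Positions become 0-based; multiallelic and unphased records are
    skipped with a logged count; duplicate rsIDs and panels with no
    usable SNPs are errors.
    """
    if not isinstance(source, (str, Path, os.PathLike)):
        # pysam wants a real file; spool streams to a temp file
        with tempfile.NamedTemporaryFile("w", suffix=".vcf", delete=False) as tmp:
            tmp.write(source.read())
            path = tmp.name
        try:
            return read_vcf_haplotypes(path)
        finally:
            os.unlink(path)

    vf = pysam.VariantFile(str(source))
    sample_names = list(vf.header.samples)
    if not sample_names:
        raise ValueError("VCF contains no samples")
    rsids: list[str] = []
    records: list[tuple[str, str, int, str, str]] = []
    columns: list[np.ndarray] = []
    skipped = 0
    seen: set[str] = set()
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            skipped += 1
            continue
        ref, alt = rec.ref, rec.alts[0]
        if len(ref) != 1 or len(alt) != 1:
            skipped += 1
            continue
        alleles: list[int] = []
        phased = True
        for s in sample_names:
            call = rec.samples[s]
            gt = call["GT"]
            if gt is None or None in gt or not call.phased:
                phased = False
                break
            alleles.extend(int(a) for a in gt)
        if not phased:
            skipped += 1
            continue
        rsid = rec.id if rec.id else f"{rec.chrom}:{rec.pos}"
        if rsid in seen:
            raise ValueError(f"duplicate rsID {rsid}")
        seen.add(rsid)
        rsids.append(rsid)
        records.append((rsid, rec.chrom, rec.start, ref, alt))  # rec.start is 0-based
        columns.append(np.array(alleles, dtype=np.uint8))
    vf.close()
    if skipped:
        logger.info("read_vcf_haplotypes: skipped %d multiallelic/unphased records", skipped)
    if not records:
        raise ValueError("no usable SNPs (no biallelic phased records)")
    n_hap = len(columns[0])
    hap_ids = [f"{s}_{i}" for s in sample_names for i in (1, 2)][:n_hap]
    snps = pd.DataFrame(records, columns=["rsid", "chrom", "pos", "ref", "alt"])
    alleles_matrix = np.stack(columns, axis=1)  # H x S
    return HaplotypePanel(haplotype_ids=hap_ids, snps=snps, alleles=alleles_matrix,
                          n_skipped=skipped)


def write_vcf_haplotypes(panel: HaplotypePanel, dest) -> None:
    """Write a panel as a minimal VCF 4.2 with phased diploid GT columns."""
    if len(panel.haplotype_ids) % 2 != 0:
        raise ValueError("need an even number of haplotypes to write diploid VCF")
    n_samples = len(panel.haplotype_ids) // 2
    sample_names = [f"S{i:04d}" for i in range(n_samples)]
    with _open_text(dest, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        chroms = panel.snps["chrom"].unique()
        for chrom in chroms:
            handle.write(f"##contig=<ID={chrom}>\n")
        handle.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        handle.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        order = np.argsort(
            panel.snps["pos"].to_numpy(), kind="stable"
        )
        # sort by chrom then pos for valid VCF
        df = panel.snps.iloc[order]
        df = df.sort_values(["chrom", "pos"], kind="stable")
        for snp_idx, row in df.iterrows():
            col = panel.alleles[:, snp_idx]
            gts = "\t".join(
                f"{col[2 * i]}|{col[2 * i + 1]}" for i in range(n_samples)
            )
            handle.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.rsid}\t{row.ref}\t{row.alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )
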