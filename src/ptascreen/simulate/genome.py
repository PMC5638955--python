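"""Synthetic genomes with strand-annotated genes and Bernoulli-placed SNPs.

Gene placement is exactly uniform over non-overlapping configurations: gene
lengths are drawn first, then start offsets follow from order statistics of
uniform draws over the remaining free space (a stick-breaking construction).
Each base is independently a SNP with probability ``snp_prob_per_bp``, which
gives a closed form for the expected number of maximal SNP-free runs of
length >= L in a window of length W:  (1 - p)^L * (1 + (W - L) p).

The emitted ground truth lists every promoter window's conserved regions
computed by a per-base brute-force scan — the independent oracle against
which the interval-based CR computation is tested.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..promoters import (
    GeneAnnotation,
    PromoterWindow,
    VariantSet,
    extract_promoter_windows,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class GenePlacementError(RuntimeError):
    """Requested genes cannot fit on the chromosome without overlap."""


@dataclass
class SyntheticGenomeSpec:
    """One synthetic chromosome: gene count/length bounds and SNP density."""

    chrom_length_bp: int
    n_genes: int
    min_gene_len_bp: int = 200
    max_gene_len_bp: int = 2000
    snp_prob_per_bp: float = 0.02
    rng_seed: int = 0
    chrom: str = "chr1"

    def __post_init__(self) -> None:
        if self.chrom_length_bp < 1 or self.n_genes < 1:
            raise ValueError("chrom_length_bp and n_genes must be positive")
        if not 1 <= self.min_gene_len_bp <= self.max_gene_len_bp:
            raise ValueError("need 1 <= min_gene_len_bp <= max_gene_len_bp")
        if not 0.0 <= self.snp_prob_per_bp <= 1.0:
            raise ValueError("snp_prob_per_bp must be a probability")


@dataclass
class GenomeTruth:
    """Ground truth shipped with a simulated genome (same rng_seed).

    ``crs_by_gene`` maps gene_id to the (start, end) conserved regions of
    its promoter window, found by scanning every window base.
    """

    windows_by_gene: dict[str, PromoterWindow]
    crs_by_gene: dict[str, list[tuple[int, int]]]
    rng_seed: int


@dataclass
class SimulatedGenome:
    spec: SyntheticGenomeSpec
    sequence: str
    genes: list[GeneAnnotation]
    variants: VariantSet
    variant_records: list[tuple[int, str, str]]  # (pos, ref, alt)
    truth: GenomeTruth


def bruteforce_conserved_regions(
    win_start: int, win_end: int, variant_positions
) -> list[tuple[int, int]]:
    """Per-base scan oracle: walk the window and collect maximal SNP-free runs."""
    snps = set(int(p) for p in variant_positions)
    regions: list[tuple[int, int]] = []
    run_start = None
    for pos in range(win_start, win_end + 1):
        if pos in snps:
            if run_start is not None:
                regions.append((run_start, pos - 1))
                run_start = None
        elif run_start is None:
            run_start = pos
    if run_start is not None:
        regions.append((run_start, win_end))
    return regions


def simulate_promoters(
    spec: SyntheticGenomeSpec, window_bp: int = 1000
) -> SimulatedGenome:
    """Simulate sequence, genes and SNPs; emit brute-force CR ground truth."""
    rng = np.random.default_rng(spec.rng_seed)
    lengths = rng.integers(spec.min_gene_len_bp, spec.max_gene_len_bp + 1, size=spec.n_genes)
    total = int(lengths.sum())
    if total > spec.chrom_length_bp:
        raise GenePlacementError(
            f"{spec.n_genes} genes of total length {total} bp exceed the "
            f"{spec.chrom_length_bp} bp chromosome"
        )
    free = spec.chrom_length_bp - total
    offsets = np.sort(rng.integers(0, free + 1, size=spec.n_genes))
    starts = offsets + np.concatenate(([0], np.cumsum(lengths[:-1]))) + 1
    strands = rng.choice(np.array(["+", "-"]), size=spec.n_genes)
    genes = [
        GeneAnnotation(spec.chrom, int(s), int(s + l - 1), str(st), f"g{i + 1:05d}")
        for i, (s, l, st) in enumerate(zip(starts, lengths, strands))
    ]

    seq_codes = rng.integers(0, 4, size=spec.chrom_length_bp)
    sequence = _BASES[seq_codes].tobytes().decode("ascii")

    snp_mask = rng.random(spec.chrom_length_bp) < spec.snp_prob_per_bp
    positions = np.flatnonzero(snp_mask) + 1
    alt_codes = (seq_codes[positions - 1] + rng.integers(1, 4, size=positions.size)) % 4
    records = [
        (int(p), sequence[p - 1], chr(_BASES[a]))
        for p, a in zip(positions, alt_codes)
    ]
    variants = VariantSet({spec.chrom: positions})

    windows = extract_promoter_windows(genes, {spec.chrom: spec.chrom_length_bp}, window_bp)
    pos_sorted = variants.positions(spec.chrom)
    windows_by_gene = {w.gene_id: w for w in windows}
    crs_by_gene: dict[str, list[tuple[int, int]]] = {}
    for w in windows:
        if w.length == 0:
            crs_by_gene[w.gene_id] = []
            continue
        lo = np.searchsorted(pos_sorted, w.start, "left")
        hi = np.searchsorted(pos_sorted, w.end, "right")
        crs_by_gene[w.gene_id] = bruteforce_conserved_regions(w.start, w.end, pos_sorted[lo:hi])
    truth = GenomeTruth(windows_by_gene, crs_by_gene, spec.rng_seed)
    return SimulatedGenome(spec, sequence, genes, variants, records, truth)


def simulate_snp_windows(
    n_windows: int, window_bp: int, snp_prob_per_bp: float, rng: np.random.Generator
) -> list[np.ndarray]:
    """Independent Bernoulli SNP position sets for stand-alone windows.

    Each returned array holds the sorted 1-based in-window SNP positions of
    one window — the fixture for run-length statistics and oracle checks
    that do not need a full chromosome around the window.
    """
    mask = rng.random((n_windows, window_bp)) < snp_prob_per_bp
    return [np.flatnonzero(row) + 1 for row in mask]


def write_genome(sim: SimulatedGenome, outdir) -> dict[str, Path]:
    """Write FASTA, GFF3 (1-based closed, strand in column 7) and minimal VCF 4.2."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom = sim.spec.chrom
    fasta = outdir / "genome.fasta"
    SeqIO.write([SeqRecord(Seq(sim.sequence), id=chrom, description="")], str(fasta), "fasta")

    gff = outdir / "genes.gff3"
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {chrom} 1 {sim.spec.chrom_length_bp}\n")
        for g in sim.genes:
            fh.write(
                f"{chrom}\tptascreen\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )

    vcf = outdir / "variants.vcf"
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={chrom},length={sim.spec.chrom_length_bp}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos, ref, alt in sim.variant_records:
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\n")
    return {"fasta": fasta, "gff3": gff, "vcf": vcf}
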