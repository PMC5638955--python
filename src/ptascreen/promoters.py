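"""Promoter SNP-free conserved regions and Cas9 target-site enumeration.

For every annotated gene, the 1 kb immediately upstream (strand-aware,
truncated at chromosome ends) is scanned against a panel of segregating
single-nucleotide variants. Maximal variant-free runs are *conserved
regions* (CRs); those longer than 30 bp are "targetable" — long enough to
hold a 20-nt protospacer plus PAM for a dCas9-based programmable
transcriptional activator. The module also enumerates candidate NGG-PAM
target sites (20-nt protospacer immediately 5' of an NGG on either strand)
within such windows and checks exact-match uniqueness across the genome.

All coordinates are 1-based closed intervals in memory and in reports; BED
exports convert to 0-based half-open.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: chromosome, 1-based closed span, strand and id."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid gene span [{self.start}, {self.end}]")
        if self.strand not in {"+", "-"}:
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-aware upstream window of a gene (1-based closed).

    A zero-length window (gene starting at the chromosome's first base) is
    represented with ``end < start`` and ``length == 0``.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def length(self) -> int:
        return max(0, self.end - self.start + 1)


@dataclass(frozen=True)
class ConservedRegion:
    """Maximal SNP-free subinterval of a promoter window (1-based closed)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class VariantSet:
    """Sorted unique 1-based SNV positions per chromosome."""

    def __init__(self, positions_by_chrom: Mapping[str, Iterable[int]]):
        self._pos = {
            chrom: np.unique(np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=np.int64))
            for chrom, p in positions_by_chrom.items()
        }

    def positions(self, chrom: str) -> np.ndarray:
        return self._pos.get(chrom, np.empty(0, dtype=np.int64))

    def chroms(self) -> list[str]:
        return list(self._pos)

    def count_in(self, chrom: str, start: int, end: int) -> int:
        p = self.positions(chrom)
        return int(np.searchsorted(p, end, "right") - np.searchsorted(p, start, "left"))

    def with_added(self, chrom: str, pos: int) -> "VariantSet":
        d = {c: p for c, p in self._pos.items()}
        d[chrom] = np.append(self.positions(chrom), pos)
        return VariantSet(d)

    @classmethod
    def from_vcf(cls, path, chroms: Sequence[str] | None = None) -> tuple["VariantSet", dict]:
        """Read SNV positions from a VCF 4.2 file.

        Only single-nucleotide records count (REF length 1 and at least one
        length-1 ALT); a multi-allelic SNV is one disqualified position and
        indel-only records are skipped with a logged count.
        """
        import pysam

        keep = set(chroms) if chroms else None
        pos: dict[str, list[int]] = {}
        stats = {"n_snv_positions": 0, "n_indels_skipped": 0, "n_multiallelic": 0}
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                if keep is not None and rec.chrom not in keep:
                    continue
                alts = rec.alts or ()
                snv_alts = [a for a in alts if a is not None and len(a) == 1 and len(rec.ref) == 1]
                if not snv_alts:
                    stats["n_indels_skipped"] += 1
                    continue
                if len(alts) > 1:
                    stats["n_multiallelic"] += 1
                pos.setdefault(rec.chrom, []).append(rec.pos)
                stats["n_snv_positions"] += 1
        if stats["n_indels_skipped"]:
            log.info("skipped %d non-SNV records", stats["n_indels_skipped"])
        return cls(pos), stats


def extract_promoter_windows(
    genes: Sequence[GeneAnnotation],
    chrom_lengths: Mapping[str, int],
    window_bp: int = 1000,
) -> list[PromoterWindow]:
    """Strand-aware upstream windows of up to ``window_bp``, abutting each gene.

    A ``+`` gene at start s gets [max(1, s - window_bp), s - 1]; a ``-`` gene
    ending at e gets [e + 1, min(L, e + window_bp)]. Windows are truncated at
    chromosome ends; genes flush with an end yield a zero-length window,
    which is emitted with a warning and skipped by downstream analysis.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    out = []
    for g in genes:
        length = chrom_lengths[g.chrom]
        if g.end > length:
            raise ValueError(f"gene {g.gene_id} exceeds chromosome {g.chrom} length {length}")
        if g.strand == "+":
            win = PromoterWindow(g.gene_id, g.chrom, max(1, g.start - window_bp), g.start - 1, "+")
        else:
            win = PromoterWindow(g.gene_id, g.chrom, g.end + 1, min(length, g.end + window_bp), "-")
        if win.length == 0:
            log.warning("gene %s has a zero-length promoter window; it will be skipped", g.gene_id)
        out.append(win)
    return out


def find_conserved_regions(window: PromoterWindow, variants: VariantSet) -> list[ConservedRegion]:
    """Maximal SNP-free runs of a window, from the sorted variant positions.

    Adjacent variant positions produce no zero-length CR; a variant-free
    window yields a single CR spanning the whole window.
    """
    if window.length == 0:
        return []
    pos = variants.positions(window.chrom)
    lo = np.searchsorted(pos, window.start, "left")
    hi = np.searchsorted(pos, window.end, "right")
    crs = []
    prev = window.start - 1
    for v in pos[lo:hi]:
        if v - prev >= 2:
            crs.append(ConservedRegion(window.gene_id, window.chrom, int(prev + 1), int(v - 1)))
        prev = int(v)
    if window.end - prev >= 1:
        crs.append(ConservedRegion(window.gene_id, window.chrom, int(prev + 1), window.end))
    return crs


def cr_offset(cr: ConservedRegion, gene: GeneAnnotation) -> int:
    """Signed position of the CR midpoint relative to the gene start.

    0 is the annotated gene start and upstream is negative, so offsets lie
    in [-window_bp, -1]. The midpoint of an even-length CR rounds toward the
    gene.
    """
    if gene.strand == "+":
        mid = (cr.start + cr.end + 1) // 2  # round toward the gene (higher coord)
        off = mid - gene.start
    else:
        mid = (cr.start + cr.end) // 2  # round toward the gene (lower coord)
        off = gene.end - mid
    if off >= 0:
        raise ValueError(f"CR [{cr.start}, {cr.end}] is not upstream of gene {gene.gene_id}")
    return int(off)


@dataclass
class CRSummary:
    """Pooled CR statistics over a set of analyzed promoters."""

    per_gene: pd.DataFrame  # gene_id, n_crs, n_targetable
    n_promoters: int
    n_crs: int
    n_targetable: int
    mean_targetable_per_promoter: float
    size_hist: pd.DataFrame  # length_bp, count — all CRs
    offset_hist: pd.DataFrame  # bin_start, bin_end, count — targetable CRs only


def summarize_crs(
    crs_by_gene: Mapping[str, Sequence[ConservedRegion]],
    genes_by_id: Mapping[str, GeneAnnotation],
    min_targetable_bp: int = 30,
    window_bp: int = 1000,
    offset_bin_bp: int = 50,
) -> CRSummary:
    """Per-gene and pooled CR statistics.

    "Targetable" is read strictly: length > ``min_targetable_bp`` (i.e.
    >= 31 bp at the default). The mean targetable count divides by *all*
    analyzed promoters, including those with zero CRs; the offset histogram
    covers targetable CRs only, in ``offset_bin_bp`` bins over
    [-window_bp, 0].
    """
    if not crs_by_gene:
        raise ValueError("no promoters to summarize")
    rows = []
    lengths: list[int] = []
    offsets: list[int] = []
    for gene_id, crs in crs_by_gene.items():
        targetable = [cr for cr in crs if cr.length > min_targetable_bp]
        rows.append({"gene_id": gene_id, "n_crs": len(crs), "n_targetable": len(targetable)})
        lengths.extend(cr.length for cr in crs)
        offsets.extend(cr_offset(cr, genes_by_id[gene_id]) for cr in targetable)
    per_gene = pd.DataFrame(rows)
    n_targetable = int(per_gene["n_targetable"].sum())
    size_counts = pd.Series(lengths, dtype=int).value_counts().sort_index()
    size_hist = pd.DataFrame({"length_bp": size_counts.index, "count": size_counts.values})
    edges = np.arange(-window_bp, 1, offset_bin_bp)
    counts, _ = np.histogram(offsets, bins=edges)
    offset_hist = pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )
    return CRSummary(
        per_gene=per_gene,
        n_promoters=len(per_gene),
        n_crs=int(per_gene["n_crs"].sum()),
        n_targetable=n_targetable,
        mean_targetable_per_promoter=n_targetable / len(per_gene),
        size_hist=size_hist,
        offset_hist=offset_hist,
    )


@dataclass(frozen=True)
class PTASite:
    """A candidate activator target: 20-nt protospacer 5' of an NGG PAM.

    ``pam_position`` is the genomic coordinate of the PAM's N base on the
    targeted strand. ``inside_cr`` means the protospacer lies entirely within
    one targetable conserved region; ``unique_in_genome`` means the 20-mer
    occurs exactly once in the supplied genome (both strands, exact match).
    """

    gene_id: str
    protospacer: str
    pam_position: int
    strand: str
    inside_cr: bool
    unique_in_genome: bool


def _count_occurrences(haystack: str, needle: str) -> int:
    n = 0
    i = haystack.find(needle)
    while i != -1:
        n += 1
        i = haystack.find(needle, i + 1)
    return n


def _genome_occurrences(genome: Mapping[str, str], kmer: str) -> int:
    rc = revcomp(kmer)
    total = 0
    for seq in genome.values():
        total += _count_occurrences(seq, kmer)
        if rc != kmer:
            total += _count_occurrences(seq, rc)
    return total


def enumerate_pta_sites(
    genome: Mapping[str, str],
    window: PromoterWindow,
    crs: Sequence[ConservedRegion],
    min_targetable_bp: int = 30,
    check_unique: bool = True,
) -> list[PTASite]:
    """All [20 nt protospacer][NGG] sites on both strands of a window.

    A site is reported when its full 20-nt protospacer lies inside the
    window (the PAM may extend past the window edge into flanking sequence).
    Candidates overlapping non-ACGT symbols are skipped with a warning.
    """
    seq = genome[window.chrom].upper()
    L = len(seq)
    targetable = [cr for cr in crs if cr.length > min_targetable_bp]
    sites: list[PTASite] = []
    skipped = 0

    def _emit(protospacer: str, pam: str, pam_pos: int, strand: str, pstart: int, pend: int) -> None:
        nonlocal skipped
        if any(b not in "ACGT" for b in protospacer + pam):
            skipped += 1
            return
        inside = any(cr.start <= pstart and pend <= cr.end for cr in targetable)
        unique = _genome_occurrences(genome, protospacer) == 1 if check_unique else False
        sites.append(PTASite(window.gene_id, protospacer, pam_pos, strand, inside, unique))

    # + strand: protospacer [p, p+19], PAM [p+20, p+22] with GG at p+21..p+22
    for p in range(window.start, window.end - 18):
        if p + 22 > L:
            break
        pam = seq[p + 19 : p + 22]
        if pam[1:3] == "GG":
            _emit(seq[p - 1 : p + 19], pam, p + 20, "+", p, p + 19)
    # - strand: genomic CCN at [q, q+2], protospacer genomic [q+3, q+22];
    # on the minus strand that reads [20 nt][NGG] with the PAM's N at q+2.
    for q in range(max(1, window.start - 3), window.end - 21):
        if q + 22 > L or q + 3 < window.start or q + 22 > window.end:
            continue
        if seq[q - 1 : q + 1] == "CC":
            pro = revcomp(seq[q + 2 : q + 22])
            pam = revcomp(seq[q - 1 : q + 2])
            _emit(pro, pam, q + 2, "-", q + 3, q + 22)
    if skipped:
        log.warning(
            "skipped %d candidate sites overlapping non-ACGT symbols in window of %s",
            skipped,
            window.gene_id,
        )
    return sites


@dataclass
class PromoterAnalysis:
    """CR analysis of a gene set against a variant panel."""

    windows: list[PromoterWindow]
    crs_by_gene: dict[str, list[ConservedRegion]]
    summary: CRSummary
    genes_by_id: dict[str, GeneAnnotation]


def analyze_promoters(
    genes: Sequence[GeneAnnotation],
    variants: VariantSet,
    chrom_lengths: Mapping[str, int],
    window_bp: int = 1000,
    min_targetable_bp: int = 30,
) -> PromoterAnalysis:
    """Windows, CRs and pooled statistics for a whole gene set.

    Zero-length windows are excluded from the analyzed promoter count;
    promoters with zero CRs still count in the mean's denominator.
    """
    windows = extract_promoter_windows(genes, chrom_lengths, window_bp)
    genes_by_id = {g.gene_id: g for g in genes}
    crs_by_gene: dict[str, list[ConservedRegion]] = {}
    kept_windows = []
    for win in windows:
        if win.length == 0:
            continue
        kept_windows.append(win)
        crs_by_gene[win.gene_id] = find_conserved_regions(win, variants)
    summary = summarize_crs(crs_by_gene, genes_by_id, min_targetable_bp, window_bp)
    return PromoterAnalysis(kept_windows, crs_by_gene, summary, genes_by_id)


def read_genes_gff3(
    path, feature_type: str = "gene", chroms: Sequence[str] | None = None
) -> list[GeneAnnotation]:
    """Load gene annotations from a GFF3 file (in-memory gffutils db)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    keep = set(chroms) if chroms else None
    genes = []
    for feat in db.features_of_type(feature_type):
        if keep is not None and feat.seqid not in keep:
            continue
        if feat.strand not in {"+", "-"}:
            log.warning("skipping %s: strand %r", feat.id, feat.strand)
            continue
        genes.append(GeneAnnotation(feat.seqid, feat.start, feat.end, feat.strand, feat.id))
    return genes


def read_genome_fasta(path, chroms: Sequence[str] | None = None) -> dict[str, str]:
    """Load chromosome sequences (uppercased) from a FASTA file."""
    from Bio import SeqIO

    keep = set(chroms) if chroms else None
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
        if keep is None or rec.id in keep
    }


def crs_to_frame(
    crs_by_gene: Mapping[str, Sequence[ConservedRegion]],
    genes_by_id: Mapping[str, GeneAnnotation],
    min_targetable_bp: int = 30,
) -> pd.DataFrame:
    """Flat CR table: gene_id, chrom, start, end, length_bp, offset_bp, targetable."""
    rows = []
    for gene_id, crs in crs_by_gene.items():
        g = genes_by_id[gene_id]
        for cr in crs:
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": cr.chrom,
                    "start": cr.start,
                    "end": cr.end,
                    "length_bp": cr.length,
                    "offset_bp": cr_offset(cr, g),
                    "targetable": cr.length > min_targetable_bp,
                }
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "length_bp", "offset_bp", "targetable"]
    )


def write_crs_bed(crs_frame: pd.DataFrame, path) -> None:
    """Write CRs as BED (0-based half-open), score = length."""
    with open(path, "w") as fh:
        for _, r in crs_frame.iterrows():
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene_id}\t{r.length_bp}\t.\n")
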