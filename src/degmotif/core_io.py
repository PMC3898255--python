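"""Genome/annotation/read I-O and genomic region classification.

Coordinate conventions
----------------------
All coordinates are 0-based half-open internally; user-facing reports are
1-based. A read's position is the genomic coordinate of its biological 5'
terminus: the leftmost base of a +-strand alignment, the rightmost base of a
−-strand alignment (BED ``chromEnd − 1``).

Region classification
---------------------
Every (chrom, strand, position) gets exactly one label among 5'UTR, CDS,
3'UTR, intron and intergenic (IGR). When isoforms disagree the priority is
CDS > 3'UTR > 5'UTR > intron; IGR applies only when no same-strand gene
overlaps the position (antisense reads over a gene are IGR on their own
strand).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from intervaltree import IntervalTree

_VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class RegionLabel(str, enum.Enum):
    """Genomic origin of an uncapped 5'-end."""

    FIVE_UTR = "5UTR"
    CDS = "CDS"
    THREE_UTR = "3UTR"
    INTRON = "intron"
    IGR = "IGR"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: isoform-conflict priority; IGR is the fallback, never competes.
_PRIORITY = [RegionLabel.CDS, RegionLabel.THREE_UTR, RegionLabel.FIVE_UTR, RegionLabel.INTRON]


class GenomeSequences(dict):
    """Per-chromosome uppercase nucleotide strings (A/C/G/T/N only)."""

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.items()}

    def slice(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Genomic subsequence [start, end), N-padded beyond chromosome bounds.

        For strand '−' the reverse complement is returned.
        """
        seq = self[chrom]
        left_pad = max(0, -start)
        right_pad = max(0, end - len(seq))
        core = seq[max(0, start) : min(len(seq), end)]
        out = "N" * left_pad + core + "N" * right_pad
        return revcomp(out) if strand == "-" else out


def read_fasta(path: str | Path) -> GenomeSequences:
    """Load a genome FASTA; uppercases and converts U to T.

    Raises ``ValueError`` on duplicate record names, an empty file, or
    characters outside {A,C,G,T,N,U}.
    """
    genome = GenomeSequences()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in genome:
            raise ValueError(f"duplicate sequence name: {record.id!r}")
        seq = str(record.seq).upper().replace("U", "T")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(
                f"non-IUPAC characters {sorted(bad)} in record {record.id!r}"
            )
        genome[record.id] = seq
    if not genome:
        raise ValueError(f"no FASTA records in {path}")
    return genome


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


@dataclass
class Transcript:
    id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted by start
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass
class NcRNA:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    ncrna_class: str = "other"  # e.g. CD_box, HACA_box, other

    @property
    def five_prime_pos(self) -> int:
        """Genomic coordinate of the feature's 5'-terminal nucleotide."""
        return self.start if self.strand == "+" else self.end - 1


class GenomeAnnotation:
    """Gene models plus ncRNA features with fast strand-aware position lookup."""

    def __init__(self, genes: list[Gene], ncrnas: list[NcRNA] | None = None):
        self.genes = genes
        self.ncrnas = ncrnas or []
        self.transcripts: list[Transcript] = [t for g in genes for t in g.transcripts]
        self._gene_trees: dict[tuple[str, str], IntervalTree] = {}
        for gene in genes:
            key = (gene.chrom, gene.strand)
            tree = self._gene_trees.setdefault(key, IntervalTree())
            if gene.end > gene.start:
                tree.addi(gene.start, gene.end, gene)

    def genes_at(self, chrom: str, strand: str, pos: int) -> list[Gene]:
        tree = self._gene_trees.get((chrom, strand))
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos)]

    def classify(self, chrom: str, strand: str, pos: int) -> RegionLabel:
        """Single region label for a position; see module docstring for priority."""
        genes = self.genes_at(chrom, strand, pos)
        if not genes:
            return RegionLabel.IGR
        labels: set[RegionLabel] = set()
        for gene in genes:
            for tx in gene.transcripts:
                labels.add(_transcript_label(tx, pos))
            if not gene.transcripts:
                labels.add(RegionLabel.INTRON)
        for label in _PRIORITY:
            if label in labels:
                return label
        return RegionLabel.INTRON

    def region_intervals(self, region: RegionLabel) -> list[tuple[str, str, int, int]]:
        """All (chrom, strand, start, end) intervals annotated with ``region``.

        For UTR/CDS these are the per-transcript sub-feature intervals; for
        intron the inter-exon gaps; IGR is not enumerable here (use
        :meth:`classify`). Transcripts without CDS fall back to their exons
        for the CDS region (they carry no derived UTRs).
        """
        out = []
        for tx in self.transcripts:
            if region is RegionLabel.CDS:
                ivs = tx.cds if (tx.cds or tx.utr5 or tx.utr3) else tx.exons
            elif region is RegionLabel.FIVE_UTR:
                ivs = tx.utr5
            elif region is RegionLabel.THREE_UTR:
                ivs = tx.utr3
            elif region is RegionLabel.INTRON:
                ivs = tx.introns()
            else:
                raise ValueError("IGR intervals are not enumerable; scan the genome")
            out.extend((tx.chrom, tx.strand, s, e) for s, e in ivs)
        return out


def _transcript_label(tx: Transcript, pos: int) -> RegionLabel:
    for s, e in tx.cds:
        if s <= pos < e:
            return RegionLabel.CDS
    for s, e in tx.utr3:
        if s <= pos < e:
            return RegionLabel.THREE_UTR
    for s, e in tx.utr5:
        if s <= pos < e:
            return RegionLabel.FIVE_UTR
    for s, e in tx.exons:
        if s <= pos < e:
            # exonic but not in any sub-feature: mRNA without CDS annotation
            # (treated as coding sequence) or annotation gaps.
            return RegionLabel.CDS if not tx.cds else RegionLabel.INTRON
    return RegionLabel.INTRON


classify_position = GenomeAnnotation.classify  # free-function alias


_NCRNA_TYPES = {
    "ncRNA",
    "snoRNA",
    "snRNA",
    "rRNA",
    "tRNA",
    "miRNA",
    "lnc_RNA",
    "ncRNA_gene",
}


def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Parse a GFF3 into gene models; derives UTRs from exon∖CDS when absent.

    GFF 1-based inclusive coordinates become 0-based half-open. Transcripts
    with CDS but no explicit UTR features get UTRs from the exon∖CDS set
    difference: on '+' the low-coordinate remainder is the 5'UTR, on '−' the
    high-coordinate remainder.
    """
    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[Gene] = []
    ncrnas: list[NcRNA] = []
    for gf in db.features_of_type("gene", order_by=("seqid", "start")):
        gene = Gene(gf.id, gf.seqid, gf.strand, gf.start - 1, gf.end)
        for tf in db.children(gf, level=1):
            if tf.featuretype in _NCRNA_TYPES:
                cls = tf.attributes.get("ncrna_class", ["other"])[0]
                ncrnas.append(
                    NcRNA(tf.id, tf.seqid, tf.strand, tf.start - 1, tf.end, cls)
                )
                continue
            if tf.featuretype not in ("mRNA", "transcript"):
                continue
            tx = _build_transcript(db, gf, tf)
            gene.transcripts.append(tx)
        if gene.transcripts:
            genes.append(gene)
    # top-level ncRNA features (no gene parent)
    for ftype in sorted(_NCRNA_TYPES):
        try:
            feats = list(db.features_of_type(ftype))
        except Exception:  # pragma: no cover - gffutils raises on unknown types
            feats = []
        for nf in feats:
            if any(True for _ in db.parents(nf)):
                continue
            cls = nf.attributes.get("ncrna_class", ["other"])[0]
            ncrnas.append(NcRNA(nf.id, nf.seqid, nf.strand, nf.start - 1, nf.end, cls))
    return GenomeAnnotation(genes, ncrnas)


def _build_transcript(db, gene_feature, tx_feature) -> Transcript:
    exons = sorted(
        (f.start - 1, f.end) for f in db.children(tx_feature, featuretype="exon")
    )
    if not exons:
        exons = [(tx_feature.start - 1, tx_feature.end)]
    cds = sorted(
        (f.start - 1, f.end) for f in db.children(tx_feature, featuretype="CDS")
    )
    utr5 = sorted(
        (f.start - 1, f.end)
        for f in db.children(tx_feature, featuretype="five_prime_UTR")
    )
    utr3 = sorted(
        (f.start - 1, f.end)
        for f in db.children(tx_feature, featuretype="three_prime_UTR")
    )
    gs, ge = gene_feature.start - 1, gene_feature.end
    for s, e in exons:
        if s < gs or e > ge:
            raise ValueError(
                f"exon [{s},{e}) outside gene span of {gene_feature.id}"
            )
    tx = Transcript(
        tx_feature.id, gene_feature.id, tx_feature.seqid, tx_feature.strand,
        exons, cds, utr5, utr3,
    )
    if cds and not utr5 and not utr3:
        tx.utr5, tx.utr3 = _derive_utrs(exons, cds, tx.strand)
    return tx


def _derive_utrs(exons, cds, strand):
    """Exon∖CDS set difference split into 5' and 3' UTR by strand."""
    cds_lo = cds[0][0]
    cds_hi = cds[-1][1]
    low, high = [], []
    for s, e in exons:
        if s < cds_lo:
            low.append((s, min(e, cds_lo)))
        if e > cds_hi:
            high.append((max(s, cds_hi), e))
    return (low, high) if strand == "+" else (high, low)


class EndCountTable:
    """Strand-aware per-position counts of uncapped 5' termini."""

    def __init__(self):
        self._counts: dict[tuple[str, str], dict[int, int]] = {}

    @property
    def total(self) -> int:
        return sum(c for d in self._counts.values() for c in d.values())

    def __len__(self) -> int:
        return sum(len(d) for d in self._counts.values())

    def add(self, chrom: str, strand: str, pos: int, count: int = 1) -> None:
        if count < 1:
            raise ValueError("count must be >= 1")
        d = self._counts.setdefault((chrom, strand), {})
        d[pos] = d.get(pos, 0) + count

    def get(self, chrom: str, strand: str, pos: int) -> int:
        return self._counts.get((chrom, strand), {}).get(pos, 0)

    def positions(self):
        """Yield (chrom, strand, pos, count), deterministically sorted."""
        for (chrom, strand) in sorted(self._counts):
            d = self._counts[(chrom, strand)]
            for pos in sorted(d):
                yield chrom, strand, pos, d[pos]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.positions()), columns=["chrom", "strand", "end_pos", "count"]
        )

    def write_bed(self, path: str | Path) -> None:
        """BED6 with one width-1 interval per end; score = count."""
        with open(path, "w") as fh:
            for chrom, strand, pos, count in self.positions():
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\tend\t{count}\t{strand}\n")

    def __eq__(self, other) -> bool:
        return isinstance(other, EndCountTable) and self._counts == other._counts


def read_end_bed(
    path: str | Path,
    *,
    score: str = "ignore",
    drop_multi: bool = False,
    genome: GenomeSequences | None = None,
) -> EndCountTable:
    """Collapse a BED6 of mapped degradome reads into 5'-end counts.

    The 5' terminus is ``chromStart`` on '+' and ``chromEnd − 1`` on '−'.
    ``score`` selects the BED score-column dialect: ``"count"`` (pre-collapsed
    read count), ``"hits"`` (genome hit count; with ``drop_multi`` reads with
    more than one hit are discarded), or ``"ignore"`` (one read per record).
    """
    if score not in ("count", "hits", "ignore"):
        raise ValueError(f"unknown BED score dialect {score!r}")
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=BED_COLUMNS, comment="#",
            dtype={"chrom": str, "name": str, "strand": str},
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=BED_COLUMNS)
    table = EndCountTable()
    if df.empty:
        return table
    if df["strand"].isna().any() or (~df["strand"].isin(["+", "-"])).any():
        raise ValueError("BED records must carry a +/- strand in column 6")
    for row in df.itertuples(index=False):
        if score == "hits" and drop_multi and int(row.score) > 1:
            continue
        count = int(row.score) if score == "count" else 1
        pos = int(row.start) if row.strand == "+" else int(row.end) - 1
        if genome is not None:
            if row.chrom not in genome:
                raise ValueError(f"chromosome {row.chrom!r} not in genome")
            if not 0 <= pos < len(genome[row.chrom]):
                raise ValueError(
                    f"position {pos} outside chromosome {row.chrom!r}"
                )
        table.add(row.chrom, row.strand, pos, count)
    return table
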