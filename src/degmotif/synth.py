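"""Seeded synthetic degradome generator with ground truth.

The generator emulates every signal class the pipeline detects, at defaults
matching the study conditions the package is validated under:

* per-transcript background decay — uncapped 5'-ends drawn Poisson(rate) at
  every exonic position (rate 0.02/nt), the uniform null the q = 1/21
  binomial test assumes;
* position-fixed truncation peaks at a fixed offset from planted motif
  instances — by default TGTACATA (a PUF-element word) in 60 of 200 3'UTRs
  with the uncapped end 3 nt upstream of the motif (motif-frame −3), peak
  heights ~ NegativeBinomial(mean 20, dispersion 5) so the binomial test is
  exercised near its threshold;
* miRNA-guided cleavage — a random 21-nt miRNA, its reverse-complement
  target planted in CDS, cleavage opposite miRNA bases 10–11 (the end at
  target base 12);
* snoRNA-like ncRNAs — C/D-box features carry the C-box word RTGATGA at
  bases 5–11 and, like H/ACA-box features, produce reads at their annotated
  5' ends; "other" ncRNAs produce none;
* adaptor mispriming — the PARE 5'-adaptor 3' word GTCCGAC planted in CDS
  with false 5'-ends starting immediately downstream of the match.

Identical config + seed gives byte-identical output files. truth.tsv records
every planted element; total counts are conserved between truth and the
emitted end table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from degmotif.core_io import (
    EndCountTable,
    Gene,
    GenomeAnnotation,
    GenomeSequences,
    NcRNA,
    RegionLabel,
    Transcript,
    revcomp,
    write_fasta,
)

READ_LENGTH = 20  # PARE reads; only the 5' terminus ever enters the analysis


@dataclass(frozen=True)
class MotifPlanting:
    word: str = "TGTACATA"
    region: RegionLabel = RegionLabel.THREE_UTR
    peak_offset: int = -3  # motif frame, no zero: end 3 nt upstream of base 1
    n_loci: int = 60
    peak_mean: float = 20.0
    peak_dispersion: float = 5.0


@dataclass(frozen=True)
class MirnaPlanting:
    sequence: str | None = None  # None → random 21-mer
    n_targets: int = 10
    peak_mean: float = 20.0
    peak_dispersion: float = 5.0


@dataclass(frozen=True)
class MisprimingPlanting:
    adaptor_3p: str = "GTCCGAC"
    n_loci: int = 40
    peak_mean: float = 20.0
    peak_dispersion: float = 5.0


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the synthetic degradome (see module docstring)."""

    seed: int
    n_chroms: int = 2
    chrom_length: int = 120_000
    n_genes: int = 200
    intron_fraction: float = 0.4
    utr5_len: int = 100
    cds_len: int = 300
    utr3_len: int = 200
    intron_len: int = 150
    n_cd_box: int = 20
    n_haca_box: int = 5
    n_other_nc: int = 5
    ncrna_len: int = 120
    motif_plantings: tuple[MotifPlanting, ...] = (MotifPlanting(),)
    mirna: MirnaPlanting | None = MirnaPlanting()
    mispriming: MisprimingPlanting | None = MisprimingPlanting()
    sno_peak_mean: float = 20.0
    sno_peak_dispersion: float = 5.0
    background_rate: float = 0.02  # Poisson rate per exonic nt
    multi_hit_fraction: float = 0.0
    bias_terminal_gc: float = 0.0  # fraction of read sequences 3'-forced to "GC"

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SynthBundle:
    config: SynthConfig
    genome: GenomeSequences
    annotation: GenomeAnnotation
    table: EndCountTable
    reads: list[tuple[str, str, int, int, str]]  # chrom, strand, end, hits, seq
    truth: pd.DataFrame
    mirna_sites: list[tuple[str, str, int]]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "annotation.gff3",
            "ends": outdir / "ends.bed",
            "reads_fa": outdir / "reads.fa",
            "reads_bed": outdir / "reads.bed",
            "truth": outdir / "truth.tsv",
            "mirna_sites": outdir / "mirna_sites.bed",
        }
        write_fasta(self.genome, paths["genome"])
        write_gff3(self.annotation, paths["annotation"])
        self.table.write_bed(paths["ends"])
        with open(paths["reads_fa"], "w") as fh:
            for i, (_, _, _, _, seq) in enumerate(self.reads):
                fh.write(f">read{i:06d}\n{seq}\n")
        with open(paths["reads_bed"], "w") as fh:
            for i, (chrom, strand, end, hits, _) in enumerate(self.reads):
                start = end if strand == "+" else end - READ_LENGTH + 1
                fh.write(
                    f"{chrom}\t{start}\t{start + READ_LENGTH}\tread{i:06d}\t{hits}\t{strand}\n"
                )
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        with open(paths["mirna_sites"], "w") as fh:
            for chrom, strand, pos in self.mirna_sites:
                fh.write(f"{chrom}\t{pos}\t{pos + 1}\tmirna_cleavage\t0\t{strand}\n")
        return paths


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Serialize gene models and ncRNA features as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in annotation.genes:
            fh.write(_row(gene.chrom, "gene", gene.start, gene.end, gene.strand, f"ID={gene.id}"))
            for tx in gene.transcripts:
                s, e = tx.span
                fh.write(_row(tx.chrom, "mRNA", s, e, tx.strand, f"ID={tx.id};Parent={gene.id}"))
                for kind, ivs in (
                    ("exon", tx.exons),
                    ("five_prime_UTR", tx.utr5),
                    ("CDS", tx.cds),
                    ("three_prime_UTR", tx.utr3),
                ):
                    for i, (a, b) in enumerate(ivs):
                        fh.write(
                            _row(tx.chrom, kind, a, b, tx.strand,
                                 f"ID={tx.id}.{kind}.{i};Parent={tx.id}")
                        )
        for nc in annotation.ncrnas:
            fh.write(
                _row(nc.chrom, "ncRNA", nc.start, nc.end, nc.strand,
                     f"ID={nc.id};ncrna_class={nc.ncrna_class}")
            )


def _row(chrom, kind, start0, end0, strand, attrs) -> str:
    return f"{chrom}\tdegmotif\t{kind}\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}\n"


def _mirror(intervals, lo, hi):
    """Reflect 0-based half-open intervals within [lo, hi)."""
    return sorted((lo + (hi - b), lo + (hi - a)) for a, b in intervals)


def _build_gene(idx: int, chrom: str, start: int, strand: str, has_intron: bool,
                cfg: SynthConfig) -> Gene:
    u5, cds_l, u3, il = cfg.utr5_len, cfg.cds_len, cfg.utr3_len, cfg.intron_len
    s = start
    if has_intron:
        half = cds_l // 2
        exons = [(s, s + u5 + half), (s + u5 + half + il, s + u5 + cds_l + il + u3)]
        cds = [(s + u5, s + u5 + half), (s + u5 + half + il, s + u5 + cds_l + il)]
        utr3 = [(s + u5 + cds_l + il, s + u5 + cds_l + il + u3)]
    else:
        exons = [(s, s + u5 + cds_l + u3)]
        cds = [(s + u5, s + u5 + cds_l)]
        utr3 = [(s + u5 + cds_l, s + u5 + cds_l + u3)]
    utr5 = [(s, s + u5)]
    end = exons[-1][1]
    if strand == "-":
        exons = _mirror(exons, s, end)
        cds = _mirror(cds, s, end)
        utr5 = _mirror(utr5, s, end)
        utr3 = _mirror(utr3, s, end)
    gid = f"gene{idx:04d}"
    tx = Transcript(f"{gid}.1", gid, chrom, strand, exons, cds, utr5, utr3)
    return Gene(gid, chrom, strand, s, end, [tx])


def _plant_word(chrom_seq: list[str], anchor: int, strand: str, word: str) -> None:
    """Write ``word`` so its base 1 sits at ``anchor`` on ``strand``."""
    if strand == "+":
        for i, b in enumerate(word):
            chrom_seq[anchor + i] = b
    else:
        rc = revcomp(word)
        for i, b in enumerate(rc):
            chrom_seq[anchor - len(word) + 1 + i] = b


def _frame_to_genomic(anchor: int, strand: str, offset: int) -> int:
    if offset == 0:
        raise ValueError("no-zero frame")
    d = offset - 1 if offset > 0 else offset
    return anchor + d if strand == "+" else anchor - d


def _nb_count(rng, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate(config: SynthConfig) -> SynthBundle:
    """Generate the full synthetic bundle (deterministic for a given seed)."""
    rng = np.random.default_rng(config.seed)
    cfg = config
    # --- genome scaffold and gene layout -------------------------------
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    chrom_seqs = {
        c: list("".join(rng.choice(list("ACGT"), size=cfg.chrom_length)))
        for c in chrom_names
    }
    slots_per_chrom = -(-cfg.n_genes // cfg.n_chroms)
    slot = cfg.chrom_length // slots_per_chrom
    gene_len_max = cfg.utr5_len + cfg.cds_len + cfg.intron_len + cfg.utr3_len
    if slot < gene_len_max + 450:
        raise ValueError("chromosomes too short for the requested gene count")
    genes: list[Gene] = []
    for i in range(cfg.n_genes):
        chrom = chrom_names[i % cfg.n_chroms]
        slot_start = (i // cfg.n_chroms) * slot
        strand = "+" if rng.random() < 0.5 else "-"
        has_intron = rng.random() < cfg.intron_fraction
        genes.append(_build_gene(i, chrom, slot_start + 200, strand, has_intron, cfg))
    # --- ncRNAs in intergenic slot tails -------------------------------
    ncrnas: list[NcRNA] = []
    classes = (
        ["CD_box"] * cfg.n_cd_box
        + ["HACA_box"] * cfg.n_haca_box
        + ["other"] * cfg.n_other_nc
    )
    n_nc = len(classes)
    if n_nc > cfg.n_genes:
        raise ValueError("more ncRNAs than intergenic slots available")
    for j, cls in enumerate(classes):
        chrom = chrom_names[j % cfg.n_chroms]
        slot_start = (j // cfg.n_chroms) * slot
        start = slot_start + slot - cfg.ncrna_len - 60
        strand = "+" if rng.random() < 0.5 else "-"
        nc = NcRNA(f"nc{j:03d}", chrom, strand, start, start + cfg.ncrna_len, cls)
        if cls == "CD_box":
            r = "A" if rng.random() < 0.5 else "G"
            cbox_anchor = _frame_to_genomic(nc.five_prime_pos, strand, 5)
            _plant_word(chrom_seqs[chrom], cbox_anchor, strand, r + "TGATGA")
        ncrnas.append(nc)

    table = EndCountTable()
    truth_rows: list[dict] = []
    planted_ends: list[tuple[str, str, int, int]] = []  # chrom,strand,end,count

    def record(cls, chrom, strand, anchor, end, count, label):
        truth_rows.append(
            {
                "class": cls,
                "chrom": chrom,
                "strand": strand,
                "anchor_pos": anchor + 1 if anchor is not None else -1,
                "end_pos": end + 1 if end is not None else -1,
                "count": count,
                "label": label,
            }
        )
        if count > 0 and end is not None:
            table.add(chrom, strand, end, count)
            planted_ends.append((chrom, strand, end, count))

    # --- snoRNA-like 5'-end peaks --------------------------------------
    for nc in ncrnas:
        if nc.ncrna_class == "other":
            continue
        count = _nb_count(rng, cfg.sno_peak_mean, cfg.sno_peak_dispersion)
        record("sno_5p", nc.chrom, nc.strand, nc.five_prime_pos,
               nc.five_prime_pos if count else None, count, nc.id)

    # --- transcript pools for plantings (disjoint) ----------------------
    order = rng.permutation(cfg.n_genes)
    cursor = 0

    def take(n: int) -> list[Gene]:
        nonlocal cursor
        if cursor + n > len(order):
            raise ValueError("plantings exceed available loci")
        picked = [genes[k] for k in order[cursor : cursor + n]]
        cursor += n
        return picked

    # --- motif-associated truncation peaks ------------------------------
    for planting in cfg.motif_plantings:
        for gene in take(planting.n_loci):
            tx = gene.transcripts[0]
            ivs = {
                RegionLabel.THREE_UTR: tx.utr3,
                RegionLabel.FIVE_UTR: tx.utr5,
                RegionLabel.CDS: tx.cds,
            }.get(planting.region)
            if not ivs:
                raise ValueError(f"region {planting.region} not plantable")
            iv = max(ivs, key=lambda se: se[1] - se[0])
            w = len(planting.word)
            lo, hi = iv[0] + 15, iv[1] - 15 - w
            if hi <= lo:
                raise ValueError("region interval too short for planting")
            pos = int(rng.integers(lo, hi))
            anchor = pos if tx.strand == "+" else pos + w - 1
            _plant_word(chrom_seqs[tx.chrom], anchor, tx.strand, planting.word)
            end = _frame_to_genomic(anchor, tx.strand, planting.peak_offset)
            count = _nb_count(rng, planting.peak_mean, planting.peak_dispersion)
            record("motif_peak", tx.chrom, tx.strand, anchor,
                   end if count else None, count, planting.word)

    # --- miRNA-guided cleavage ------------------------------------------
    mirna_sites: list[tuple[str, str, int]] = []
    if cfg.mirna is not None and cfg.mirna.n_targets > 0:
        mirna_seq = cfg.mirna.sequence or "".join(rng.choice(list("ACGT"), size=21))
        target = revcomp(mirna_seq)
        for gene in take(cfg.mirna.n_targets):
            tx = gene.transcripts[0]
            iv = max(tx.cds, key=lambda se: se[1] - se[0])
            lo, hi = iv[0] + 15, iv[1] - 15 - 21
            pos = int(rng.integers(lo, hi))
            anchor = pos if tx.strand == "+" else pos + 20
            _plant_word(chrom_seqs[tx.chrom], anchor, tx.strand, target)
            # slicing between target bases 11 and 12 (opposite miRNA 10-11):
            # the 3' fragment's uncapped end is target base 12
            end = _frame_to_genomic(anchor, tx.strand, 12)
            mirna_sites.append((tx.chrom, tx.strand, end))
            count = _nb_count(rng, cfg.mirna.peak_mean, cfg.mirna.peak_dispersion)
            record("mirna_cleavage", tx.chrom, tx.strand, anchor,
                   end if count else None, count, mirna_seq)

    # --- adaptor mispriming ----------------------------------------------
    if cfg.mispriming is not None and cfg.mispriming.n_loci > 0:
        word = cfg.mispriming.adaptor_3p
        for gene in take(cfg.mispriming.n_loci):
            tx = gene.transcripts[0]
            iv = max(tx.cds, key=lambda se: se[1] - se[0])
            lo, hi = iv[0] + 15, iv[1] - 15 - len(word)
            pos = int(rng.integers(lo, hi))
            anchor = pos if tx.strand == "+" else pos + len(word) - 1
            _plant_word(chrom_seqs[tx.chrom], anchor, tx.strand, word)
            end = _frame_to_genomic(anchor, tx.strand, len(word) + 1)
            count = _nb_count(rng, cfg.mispriming.peak_mean, cfg.mispriming.peak_dispersion)
            record("artifact", tx.chrom, tx.strand, anchor,
                   end if count else None, count, word)

    # --- uniform background decay along transcripts ----------------------
    background: list[tuple[str, str, int, int]] = []  # chrom,strand,end,hits
    n_background = 0
    n_multi = 0
    if cfg.background_rate > 0:
        for gene in genes:
            tx = gene.transcripts[0]
            for s, e in tx.exons:
                draws = rng.poisson(cfg.background_rate, size=e - s)
                for off in np.flatnonzero(draws):
                    for _ in range(int(draws[off])):
                        hits = 1
                        if cfg.multi_hit_fraction > 0 and rng.random() < cfg.multi_hit_fraction:
                            hits = 2
                            n_multi += 1
                            background.append((tx.chrom, tx.strand, s + int(off), hits))
                            continue
                        n_background += 1
                        table.add(tx.chrom, tx.strand, s + int(off), 1)
                        background.append((tx.chrom, tx.strand, s + int(off), 1))
    truth_rows.append(
        {"class": "background", "chrom": ".", "strand": ".", "anchor_pos": -1,
         "end_pos": -1, "count": n_background, "label": "uniform_decay"}
    )
    if n_multi:
        truth_rows.append(
            {"class": "multi_hit", "chrom": ".", "strand": ".", "anchor_pos": -1,
             "end_pos": -1, "count": n_multi, "label": "dropped_from_ends"}
        )

    genome = GenomeSequences({c: "".join(s) for c, s in chrom_seqs.items()})
    annotation = GenomeAnnotation(genes, ncrnas)

    # --- per-read sequences (20 nt from each end) ------------------------
    reads: list[tuple[str, str, int, int, str]] = []
    for chrom, strand, end, count in planted_ends:
        seq = _read_seq(genome, chrom, strand, end)
        reads.extend([(chrom, strand, end, 1, seq)] * count)
    for chrom, strand, end, hits in background:
        reads.append((chrom, strand, end, hits, _read_seq(genome, chrom, strand, end)))
    if cfg.bias_terminal_gc > 0:
        reads = [
            (c, st, e, h, s[:-2] + "GC" if rng.random() < cfg.bias_terminal_gc else s)
            for c, st, e, h, s in reads
        ]

    truth = pd.DataFrame(
        truth_rows,
        columns=["class", "chrom", "strand", "anchor_pos", "end_pos", "count", "label"],
    )
    return SynthBundle(cfg, genome, annotation, table, reads, truth, mirna_sites)


def _read_seq(genome: GenomeSequences, chrom: str, strand: str, end: int) -> str:
    if strand == "+":
        return genome.slice(chrom, end, end + READ_LENGTH, "+")
    return genome.slice(chrom, end - READ_LENGTH + 1, end + 1, "-")


def truth_peaks(truth: pd.DataFrame, min_count: int = 1) -> set[tuple[str, str, int]]:
    """Planted end positions (0-based) with count ≥ min_count."""
    planted = truth[
        truth["class"].isin(["motif_peak", "mirna_cleavage", "sno_5p", "artifact"])
        & (truth["count"] >= min_count)
        & (truth["end_pos"] > 0)
    ]
    return {
        (r.chrom, r.strand, int(r.end_pos) - 1) for r in planted.itertuples(index=False)
    }


def truth_compare(
    called_peaks,
    truth: pd.DataFrame,
    motif_models=None,
    min_count: int = 1,
) -> dict:
    """Recovery metrics of pipeline outputs against the ground truth.

    A called peak matches the truth iff it sits at a planted (chrom, strand,
    position). When ``motif_models`` is given, each planted motif word is
    checked for recovery: some model's consensus expansion must contain the
    word and the model's end offset (motif frame) must equal the planted
    peak offset.
    """
    from degmotif.motif import iupac_match

    truth_set = truth_peaks(truth, min_count=min_count)
    called = {(p.chrom, p.strand, p.end_pos) for p in called_peaks}
    tp = len(called & truth_set)
    metrics = {
        "n_truth": len(truth_set),
        "n_called": len(called),
        "sensitivity": tp / len(truth_set) if truth_set else float("nan"),
        "precision": tp / len(called) if called else float("nan"),
    }
    if motif_models is not None:
        planted = truth[(truth["class"] == "motif_peak") & (truth["end_pos"] > 0)]
        for word in sorted(planted["label"].unique()):
            rows = planted[planted["label"] == word]
            planted_offset = _motif_frame_offset(rows.iloc[0])
            recovered = any(
                m.width == len(word)
                and iupac_match(m.consensus, word)
                and m.peak_offset_in_motif_frame == planted_offset
                for m in motif_models
            )
            metrics[f"motif_recovered[{word}]"] = recovered
    return metrics


def _motif_frame_offset(row) -> int:
    """Planted peak offset in the motif frame from a truth row."""
    anchor = int(row["anchor_pos"]) - 1
    end = int(row["end_pos"]) - 1
    d = (end - anchor) if row["strand"] == "+" else (anchor - end)
    return d + 1 if d >= 0 else d
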