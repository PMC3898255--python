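"""Library-quality diagnostics for degradome data.

Two failure modes seen in real libraries are screened for:

* **3'-terminal base-composition bias** — MmeI digestion leaves a 2-nt
  overhang, and ligation selectivity can skew the last bases of every read
  (e.g. a library whose unique reads overwhelmingly end in "GC"). The
  composition of the last *k* nucleotides over unique read sequences is
  tabulated against a transcriptome background.
* **Adaptor mispriming** — capped transcripts whose internal sequence
  anneals to the 3' end of the 5' adaptor primer are amplified without
  adaptor ligation, creating false uncapped 5'-ends starting immediately
  downstream of the genomic adaptor match. Anchoring a MORPH at adaptor
  matches makes these visible as a pile-up at frame +|adaptor|+1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from degmotif.core_io import EndCountTable, GenomeAnnotation, GenomeSequences, RegionLabel
from degmotif.morph import (
    MorphMatrix,
    MorphSummary,
    anchors_from_motif,
    build_matrix,
    summarize,
)

#: 3'-terminal word of the 5' adaptor primer, by library protocol
ADAPTOR_PRESETS = {
    "PARE": "GTCCGAC",
    "PARE_long": "AGTCCGAC",
    "degradome-seq": "GATCCAAC",
    "GMUCT": "GACGATC",
}


def terminal_composition(reads: list[str], k: int = 5) -> pd.DataFrame:
    """A/C/G/T fractions at the last ``k`` positions of unique read sequences.

    Rows are terminal positions −k..−1 (−1 = the 3'-terminal base); columns
    A/C/G/T sum to 1 per row. Duplicate read sequences count once.
    """
    unique = sorted({r.upper().replace("U", "T") for r in reads})
    if not unique:
        raise ValueError("no reads supplied")
    short = [r for r in unique if len(r) < k]
    if short:
        raise ValueError(f"{len(short)} unique reads shorter than k={k}")
    counts = np.zeros((k, 4))
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for read in unique:
        for j in range(k):
            b = read[len(read) - k + j]
            if b in base_idx:
                counts[j, base_idx[b]] += 1
    fractions = counts / counts.sum(axis=1, keepdims=True)
    return pd.DataFrame(
        fractions, index=[f"{j - k}" for j in range(k)], columns=list("ACGT")
    )


def transcript_composition(
    genome: GenomeSequences, annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Overall base composition of annotated transcript (exonic) sequence.

    Single-row background table matching ``terminal_composition`` columns.
    """
    counts = np.zeros(4)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for tx in annotation.transcripts:
        for s, e in tx.exons:
            seq = genome.slice(tx.chrom, s, e, tx.strand)
            for b in seq:
                if b in base_idx:
                    counts[base_idx[b]] += 1
    if counts.sum() == 0:
        raise ValueError("annotation contains no exonic sequence")
    return pd.DataFrame([counts / counts.sum()], index=["cDNA"], columns=list("ACGT"))


@dataclass
class ArtifactReport:
    adaptor_3p: str
    n_anchors: int
    matrix: MorphMatrix
    summary: MorphSummary
    flagged: np.ndarray  # per retained locus: modal column == +|adaptor|+1
    flagged_fraction: float


def artifact_screen(
    table: EndCountTable,
    genome: GenomeSequences,
    annotation: GenomeAnnotation,
    adaptor_3p: str = ADAPTOR_PRESETS["PARE"],
    region: RegionLabel = RegionLabel.CDS,
    min_total: int = 5,
    filter_on: bool = True,
) -> ArtifactReport:
    """Screen for false 5'-ends immediately downstream of adaptor matches.

    Anchors every occurrence of the adaptor 3'-end word in the region, builds
    a MORPH, and flags each retained locus whose modal column is frame
    +|adaptor|+1 (the first base after the match). With no retained loci the
    flagged fraction is 0.
    """
    if len(adaptor_3p) < 5:
        raise ValueError("adaptor 3'-end word must be at least 5 nt")
    anchors = anchors_from_motif(annotation, genome, adaptor_3p, region)
    flag_col = len(adaptor_3p) + 1
    if not anchors.anchors:
        matrix = MorphMatrix([], np.empty((0, 20)), np.array([]), 10, 0)
        summary = summarize(matrix, allow_empty=True)
        return ArtifactReport(adaptor_3p, 0, matrix, summary, np.array([]), 0.0)
    halfwidth = max(10, flag_col)
    matrix = build_matrix(
        anchors, table, halfwidth=halfwidth, min_total=min_total, filter_on=filter_on
    )
    summary = summarize(matrix, allow_empty=True)
    if matrix.n_retained == 0:
        return ArtifactReport(
            adaptor_3p, len(anchors), matrix, summary, np.array([]), 0.0
        )
    col = matrix.column_index(flag_col)
    flagged = matrix.values.argmax(axis=1) == col
    return ArtifactReport(
        adaptor_3p,
        len(anchors),
        matrix,
        summary,
        flagged,
        float(flagged.mean()),
    )
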