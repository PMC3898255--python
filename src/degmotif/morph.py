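"""Motif-Oriented Read Positioning Heat maps (MORPH).

Genome-wide "reverse" analysis: given anchors — every occurrence of a motif
in a genomic region, or the 5'-terminal nucleotide of a feature class — the
uncapped-read 5'-end counts in a 20-position window around each anchor are
collected, normalized per locus to fractions, optionally filtered (total
reads must exceed 5), clustered by Ward's method, and rendered as a heat map.

Frame: the anchor base (motif base 1 / feature 5'-end) is frame position +1;
there is no position 0. The 20 columns are −10..−1 and +1..+10, oriented
5'→3' on the anchor's strand; a read's position is its 5' terminus. With
this split both the upstream truncation peaks (e.g. −3 for PUF sites) and
the downstream adaptor-artifact peak (+8 after a 7-nt adaptor match) fall
inside the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from degmotif.core_io import (
    EndCountTable,
    GenomeAnnotation,
    GenomeSequences,
    RegionLabel,
)
from degmotif.motif import iupac_expand


@dataclass(frozen=True)
class Anchor:
    chrom: str
    strand: str
    anchor_pos: int  # 0-based genomic coordinate of frame position +1
    label: str = ""


@dataclass
class AnchorSet:
    anchors: list[Anchor]
    source: str = "motif"  # "motif" or "feature-5prime"

    def __len__(self) -> int:
        return len(self.anchors)


def frame_offsets(halfwidth: int = 10) -> list[int]:
    """The signed no-zero column frame: −h..−1, +1..+h."""
    return [o for o in range(-halfwidth, halfwidth + 1) if o != 0]


def frame_to_genomic(anchor: Anchor, offset: int) -> int:
    """Genomic coordinate of a frame offset (no zero; +1 = the anchor base)."""
    if offset == 0:
        raise ValueError("frame has no position 0")
    d = offset - 1 if offset > 0 else offset
    return anchor.anchor_pos + d if anchor.strand == "+" else anchor.anchor_pos - d


def _scan_iupac(seq: str, consensus: str) -> list[int]:
    from degmotif.motif import IUPAC

    cols = [IUPAC[c] for c in consensus.upper()]
    w = len(cols)
    return [
        j
        for j in range(len(seq) - w + 1)
        if all(b in col for b, col in zip(seq[j : j + w], cols))
    ]


def anchors_from_motif(
    annotation: GenomeAnnotation,
    genome: GenomeSequences,
    consensus: str,
    region: RegionLabel,
) -> AnchorSet:
    """One anchor per motif occurrence in a genomic region (base 1 position).

    Non-IGR regions are scanned on the transcript strand over each annotated
    region interval (matches spanning a splice junction are not considered);
    IGR scans both strands of the whole genome and keeps matches whose first
    base classifies as intergenic on the match strand. Overlapping matches
    are all kept; anchors are unique per (chrom, strand, position).
    """
    iupac_expand(consensus)  # validate
    w = len(consensus)
    found: set[Anchor] = set()
    if region is RegionLabel.IGR:
        for chrom, seq in genome.items():
            for strand in ("+", "-"):
                scan_seq = seq if strand == "+" else _rc(seq)
                for j in _scan_iupac(scan_seq, consensus):
                    pos = j if strand == "+" else len(seq) - 1 - j
                    if annotation.classify(chrom, strand, pos) is RegionLabel.IGR:
                        found.add(Anchor(chrom, strand, pos, consensus))
    else:
        for chrom, strand, start, end in annotation.region_intervals(region):
            sub = genome.slice(chrom, start, end, strand)
            for j in _scan_iupac(sub, consensus):
                if strand == "+":
                    pos = start + j
                else:
                    pos = end - 1 - j
                found.add(Anchor(chrom, strand, pos, consensus))
    anchors = sorted(found, key=lambda a: (a.chrom, a.strand, a.anchor_pos))
    return AnchorSet(anchors, source="motif")


def _rc(seq: str) -> str:
    from degmotif.core_io import revcomp

    return revcomp(seq)


def anchors_from_features(
    annotation: GenomeAnnotation, feature_class: str | None = None
) -> AnchorSet:
    """Anchors at the 5'-terminal nucleotide of ncRNA features.

    ``feature_class`` restricts to one class label (e.g. "CD_box"); None
    takes every ncRNA feature.
    """
    anchors = []
    seen = set()
    for nc in annotation.ncrnas:
        if feature_class is not None and nc.ncrna_class != feature_class:
            continue
        a = Anchor(nc.chrom, nc.strand, nc.five_prime_pos, nc.id)
        if (a.chrom, a.strand, a.anchor_pos) not in seen:
            seen.add((a.chrom, a.strand, a.anchor_pos))
            anchors.append(a)
    anchors.sort(key=lambda a: (a.chrom, a.strand, a.anchor_pos))
    return AnchorSet(anchors, source="feature-5prime")


@dataclass
class MorphMatrix:
    """Loci × 20 signed-offset columns of per-locus normalized read fractions."""

    anchors: list[Anchor]  # retained rows, in input anchor order
    values: np.ndarray  # shape (n_retained, 2*halfwidth)
    row_totals: np.ndarray  # pre-normalization totals of retained rows
    halfwidth: int = 10
    n_total_anchors: int = 0  # anchors before filtering
    linkage: np.ndarray | None = None
    leaf_order: np.ndarray | None = None

    @property
    def offsets(self) -> list[int]:
        return frame_offsets(self.halfwidth)

    @property
    def n_retained(self) -> int:
        return len(self.anchors)

    def column_index(self, offset: int) -> int:
        return self.offsets.index(offset)


def build_matrix(
    anchors: AnchorSet,
    table: EndCountTable,
    halfwidth: int = 10,
    min_total: int = 5,
    filter_on: bool = True,
) -> MorphMatrix:
    """Per-locus normalized read profiles around anchors.

    Rows with zero reads in the window are always dropped; with the filter on,
    rows whose total is ≤ ``min_total`` are dropped ("greater than five").
    Retained rows are divided by their total, so each sums to 1. The result
    is a pure function of anchor/read coordinates (input order irrelevant).
    """
    if halfwidth < 1:
        raise ValueError("halfwidth must be >= 1")
    if not anchors.anchors:
        raise ValueError("anchor set is empty")
    offsets = frame_offsets(halfwidth)
    kept_anchors, rows, totals = [], [], []
    for anchor in anchors.anchors:
        counts = np.array(
            [
                table.get(anchor.chrom, anchor.strand, frame_to_genomic(anchor, o))
                for o in offsets
            ],
            dtype=float,
        )
        total = counts.sum()
        if total == 0:
            continue
        if filter_on and total <= min_total:
            continue
        kept_anchors.append(anchor)
        rows.append(counts / total)
        totals.append(total)
    values = (
        np.vstack(rows) if rows else np.empty((0, len(offsets)), dtype=float)
    )
    return MorphMatrix(
        kept_anchors,
        values,
        np.asarray(totals),
        halfwidth,
        n_total_anchors=len(anchors.anchors),
    )


def ward_cluster(matrix: MorphMatrix, variant: str = "D2") -> MorphMatrix:
    """Ward-linkage agglomerative clustering of the normalized rows.

    Euclidean distances; ``variant`` "D2" is the minimum-variance criterion
    on the given distances (scipy/ hclust ward.D2), "D" applies the same
    Lance–Williams update to squared distances (hclust ward.D). Leaf order is
    the standard dendrogram order with input-index tie-breaking, so repeated
    runs are identical.
    """
    n = matrix.n_retained
    if n == 0:
        raise ValueError("no loci retained")
    if n == 1:
        matrix.linkage = np.empty((0, 4))
        matrix.leaf_order = np.array([0])
        return matrix
    dists = pdist(matrix.values, metric="euclidean")
    if variant == "D":
        dists = dists**2
    elif variant != "D2":
        raise ValueError("ward variant must be 'D' or 'D2'")
    Z = linkage(dists, method="ward")
    matrix.linkage = Z
    matrix.leaf_order = leaves_list(Z)
    return matrix


@dataclass
class MorphSummary:
    offsets: list[int]
    mean_profile: np.ndarray
    modal_fraction: np.ndarray  # share of loci whose maximum is at each offset
    n_retained: int
    n_total: int

    @property
    def top_modal_offset(self) -> int:
        return self.offsets[int(np.argmax(self.modal_fraction))]

    @property
    def top_modal_fraction(self) -> float:
        return float(self.modal_fraction.max()) if self.n_retained else 0.0

    def modal_fraction_at(self, offset: int) -> float:
        return float(self.modal_fraction[self.offsets.index(offset)])


def summarize(matrix: MorphMatrix, allow_empty: bool = False) -> MorphSummary:
    """Column means and per-column modal-locus fractions.

    A row ties for its maximum at several columns count once, at the most
    upstream tied column, so modal fractions sum to exactly 1 over retained
    rows (to ≤ 1 conceptually, given the single-count rule).
    """
    offsets = frame_offsets(matrix.halfwidth)
    if matrix.n_retained == 0:
        if not allow_empty:
            raise ValueError("no loci retained")
        z = np.zeros(len(offsets))
        return MorphSummary(offsets, z, z.copy(), 0, matrix.n_total_anchors)
    mean_profile = matrix.values.mean(axis=0)
    modal_counts = np.zeros(len(offsets))
    for row in matrix.values:
        modal_counts[int(np.argmax(row))] += 1  # argmax = first (most upstream) tie
    return MorphSummary(
        offsets,
        mean_profile,
        modal_counts / matrix.n_retained,
        matrix.n_retained,
        matrix.n_total_anchors,
    )


def matrix_to_frame(matrix: MorphMatrix):
    """TSV-ready table: anchor id, coordinates (1-based), total, 20 columns."""
    import pandas as pd

    cols = [f"m{o:+d}" for o in matrix.offsets]
    records = []
    for anchor, total, row in zip(matrix.anchors, matrix.row_totals, matrix.values):
        rec = {
            "anchor": anchor.label or "anchor",
            "chrom": anchor.chrom,
            "strand": anchor.strand,
            "anchor_pos": anchor.anchor_pos + 1,
            "row_total": int(total),
        }
        rec.update({c: v for c, v in zip(cols, row)})
        records.append(rec)
    return pd.DataFrame(
        records,
        columns=["anchor", "chrom", "strand", "anchor_pos", "row_total"] + cols,
    )


def linkage_to_newick(matrix: MorphMatrix) -> str:
    """Merge tree as a newick string with heights as branch lengths."""
    if matrix.linkage is None:
        raise ValueError("run ward_cluster first")
    n = matrix.n_retained
    if n == 1:
        return "(L0);"
    nodes = {i: (f"L{i}", 0.0) for i in range(n)}
    for i, (a, b, h, _) in enumerate(matrix.linkage):
        la, ha = nodes.pop(int(a))
        lb, hb = nodes.pop(int(b))
        nodes[n + i] = (f"({la}:{h - ha:.6g},{lb}:{h - hb:.6g})", float(h))
    (label, _), = nodes.values()
    return label + ";"


def render_heatmap(
    matrix: MorphMatrix,
    path,
    motif_width: int | None = None,
    title: str = "",
) -> None:
    """Render retained rows (in dendrogram leaf order) as a heat map image.

    The motif span (+1..+width) is boxed when ``motif_width`` is given; the
    retained/total locus counts are annotated above, as in published MORPH
    panels. Output format follows the file extension (png or svg).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if matrix.n_retained == 0:
        raise ValueError("no loci retained")
    order = (
        matrix.leaf_order if matrix.leaf_order is not None else np.arange(matrix.n_retained)
    )
    data = matrix.values[order]
    fig, ax = plt.subplots(
        figsize=(6, max(1.5, 0.08 * matrix.n_retained + 1.0))
    )
    im = ax.imshow(data, aspect="auto", cmap="viridis", interpolation="nearest")
    ax.set_xticks(range(len(matrix.offsets)))
    ax.set_xticklabels([str(o) for o in matrix.offsets], fontsize=6, rotation=90)
    ax.set_yticks([])
    ax.set_xlabel("position relative to anchor (anchor base = +1)")
    header = f"{title} ({matrix.n_retained}/{matrix.n_total_anchors})"
    ax.set_title(header.strip(), fontsize=9)
    if motif_width:
        start = matrix.column_index(1) - 0.5
        ax.add_patch(
            plt.Rectangle(
                (start, -0.5),
                min(motif_width, matrix.halfwidth),
                matrix.n_retained,
                fill=False,
                edgecolor="white",
                linewidth=1.2,
            )
        )
    fig.colorbar(im, ax=ax, label="normalized read fraction")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
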