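"""Calling predominant uncapped 5'-ends.

A candidate end at genomic position *p* is evaluated inside a 21-nt window
symmetrically flanking it (signed offsets −10..+10 oriented 5'→3' on the
read's strand; offset 0 is the end itself). Two conjunctive filters retain an
end as predominant:

* **dominance**: reads at the end plus the positions 1 nt up- and downstream
  must constitute at least 50% of the window total, (c₋₁+c₀+c₊₁)/n ≥ 0.5;
* **binomial significance**: with x reads at the end among n in the window
  and a uniform null placing each read at any of the 21 positions with
  probability q = 1/21, the upper tail P(X ≥ x), X ~ Binomial(n, q), must be
  below 10⁻⁵. The point mass C(n,x)qˣ(1−q)ⁿ⁻ˣ is available as an alternative
  (``pvalue_mode="point"``); the tail is never smaller than the point mass,
  so the default is the conservative choice.

Retained ends are labelled by genomic region, ends at known miRNA cleavage
sites are flagged and excluded from motif analysis, at most the top 1000 most
abundant ends per region are kept, and a 50-nt flanking window (25 nt up- and
downstream, strand-oriented; the end nucleotide is the 26th character) is
extracted for motif discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import binom

from degmotif.core_io import (
    EndCountTable,
    GenomeAnnotation,
    GenomeSequences,
    RegionLabel,
)

#: window position (1-based, of 50) holding the uncapped-end nucleotide
WINDOW_END_POS = 26
WINDOW_FLANK = 25


@dataclass(frozen=True)
class PeakTestParams:
    """Thresholds of the dominance + binomial peak filter."""

    window_size: int = 21
    q: float = 1.0 / 21.0
    dominance_min: float = 0.5
    p_threshold: float = 1e-5
    top_k: int = 1000
    mirna_tolerance: int = 0
    pvalue_mode: str = "tail"  # "tail" (P(X>=x)) or "point" (the literal mass)

    def __post_init__(self):
        if self.window_size % 2 != 1 or self.window_size < 3:
            raise ValueError("window_size must be odd and >= 3")
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if not 0 < self.dominance_min <= 1:
            raise ValueError("dominance_min must lie in (0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.pvalue_mode not in ("tail", "point"):
            raise ValueError("pvalue_mode must be 'tail' or 'point'")

    @property
    def halfwidth(self) -> int:
        return self.window_size // 2


@dataclass
class WindowProfile:
    """Counts at signed offsets −h..+h around a focal end (strand-oriented)."""

    counts: np.ndarray  # length window_size, index 0 = offset -h
    halfwidth: int

    def at(self, offset: int) -> int:
        return int(self.counts[offset + self.halfwidth])

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass
class Peak:
    """A candidate predominant uncapped 5'-end."""

    chrom: str
    strand: str
    end_pos: int  # 0-based genomic
    region: RegionLabel
    x: int  # reads at the end itself
    n: int  # reads in the 21-nt window
    dominance: float
    p_value: float
    excluded_mirna: bool = False


@dataclass
class PeakWindowSeq:
    """Strand-oriented 50-nt sequence flanking a peak (end = 26th base)."""

    peak: Peak
    sequence: str
    truncated: bool = False

    @property
    def name(self) -> str:
        return (
            f"{self.peak.chrom}:{self.peak.end_pos + 1}:{self.peak.strand}"
            f":{self.peak.region.value}"
        )


def window_profile(
    table: EndCountTable, chrom: str, strand: str, end_pos: int, halfwidth: int = 10
) -> WindowProfile:
    """Read counts at signed offsets around an end, oriented on its strand.

    Offset +1 is 1 nt 3' of the end on the read's strand (genomic ``end_pos+1``
    on '+', ``end_pos−1`` on '−'); positions beyond the chromosome contribute 0.
    """
    step = 1 if strand == "+" else -1
    counts = np.array(
        [
            table.get(chrom, strand, end_pos + step * off)
            for off in range(-halfwidth, halfwidth + 1)
        ],
        dtype=np.int64,
    )
    return WindowProfile(counts, halfwidth)


def dominance_fraction(profile: WindowProfile) -> float:
    """(c₋₁ + c₀ + c₊₁) / n over the window; undefined for an empty window."""
    n = profile.n
    if n == 0:
        raise ValueError("empty window: dominance undefined")
    return (profile.at(-1) + profile.at(0) + profile.at(1)) / n


def binom_tail(x: int, n: int, q: float) -> float:
    """Upper-tail binomial probability P(X ≥ x) for X ~ Binomial(n, q)."""
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    if not 0 <= x <= n or n < 1:
        raise ValueError("require 0 <= x <= n and n >= 1")
    if x == 0:
        return 1.0
    return float(binom.sf(x - 1, n, q))


def binom_point(x: int, n: int, q: float) -> float:
    """The point mass C(n,x) qˣ (1−q)ⁿ⁻ˣ."""
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    return float(binom.pmf(x, n, q))


def peak_pvalue(x: int, n: int, params: PeakTestParams) -> float:
    fn = binom_tail if params.pvalue_mode == "tail" else binom_point
    return fn(x, n, params.q)


def call_peaks(
    table: EndCountTable,
    annotation: GenomeAnnotation,
    params: PeakTestParams = PeakTestParams(),
) -> dict[RegionLabel, list[Peak]]:
    """Identify predominant uncapped 5'-ends, grouped by genomic region.

    Every position carrying at least one read is a candidate; a candidate is
    retained iff dominance ≥ ``dominance_min`` and P < ``p_threshold``. The
    result is deterministic and independent of input record order (candidates
    are visited in sorted coordinate order).
    """
    out: dict[RegionLabel, list[Peak]] = {label: [] for label in RegionLabel}
    for chrom, strand, pos, x in table.positions():
        profile = window_profile(table, chrom, strand, pos, params.halfwidth)
        n = profile.n
        dom = dominance_fraction(profile)
        if dom < params.dominance_min:
            continue
        p = peak_pvalue(x, n, params)
        if p >= params.p_threshold:
            continue
        region = annotation.classify(chrom, strand, pos)
        out[region].append(Peak(chrom, strand, pos, region, x, n, dom, p))
    return out


def stage_counts(
    table: EndCountTable,
    annotation: GenomeAnnotation,
    params: PeakTestParams = PeakTestParams(),
) -> dict[str, int]:
    """Per-filter accounting: candidates, dominance-pass, P-pass (both)."""
    candidates = dominance_pass = both = 0
    for chrom, strand, pos, x in table.positions():
        candidates += 1
        profile = window_profile(table, chrom, strand, pos, params.halfwidth)
        if dominance_fraction(profile) < params.dominance_min:
            continue
        dominance_pass += 1
        if peak_pvalue(x, profile.n, params) < params.p_threshold:
            both += 1
    return {
        "candidates": candidates,
        "dominance_pass": dominance_pass,
        "significant": both,
    }


def read_site_bed(path) -> list[tuple[str, str, int]]:
    """Strand-aware single positions from a BED of known cleavage sites."""
    import pandas as pd

    from degmotif.core_io import BED_COLUMNS

    df = pd.read_csv(path, sep="\t", header=None, names=BED_COLUMNS, comment="#")
    sites = []
    for row in df.itertuples(index=False):
        pos = int(row.start) if row.strand == "+" else int(row.end) - 1
        sites.append((str(row.chrom), str(row.strand), pos))
    return sites


def filter_mirna_sites(
    peaks: list[Peak],
    exclusion: list[tuple[str, str, int]],
    tolerance: int = 0,
) -> list[Peak]:
    """Flag peaks at known miRNA cleavage sites (same strand, ±tolerance).

    Flagged peaks stay in the returned list (for the full report) with
    ``excluded_mirna=True``; downstream motif analysis omits them. Flagging
    never alters a peak's p-value or dominance.
    """
    index: set[tuple[str, str, int]] = set()
    for chrom, strand, pos in exclusion:
        for d in range(-tolerance, tolerance + 1):
            index.add((chrom, strand, pos + d))
    for peak in peaks:
        peak.excluded_mirna = (peak.chrom, peak.strand, peak.end_pos) in index
    return peaks


def select_top(peaks: list[Peak], params: PeakTestParams = PeakTestParams()) -> list[Peak]:
    """Keep the ``top_k`` most abundant ends (by x; ties by coordinate)."""
    ranked = sorted(peaks, key=lambda p: (-p.x, p.chrom, p.end_pos, p.strand))
    return ranked[: params.top_k]


def extract_windows(
    peaks: list[Peak], genome: GenomeSequences, flank: int = WINDOW_FLANK
) -> list[PeakWindowSeq]:
    """50-nt strand-oriented windows around peaks; end = character ``flank+1``.

    On '+' the genomic slice is [p−flank, p+flank); on '−' it is the reverse
    complement of [p−flank+1, p+flank+1). Windows truncated at a chromosome
    edge are N-padded and flagged.
    """
    out = []
    for peak in peaks:
        if peak.chrom not in genome:
            raise KeyError(f"chromosome {peak.chrom!r} missing from genome")
        p = peak.end_pos
        if peak.strand == "+":
            start, end = p - flank, p + flank
        else:
            start, end = p - flank + 1, p + flank + 1
        seq = genome.slice(peak.chrom, start, end, peak.strand)
        truncated = "N" in seq and (
            start < 0 or end > len(genome[peak.chrom])
        )
        out.append(PeakWindowSeq(peak, seq, truncated))
    return out


def write_windows_fasta(windows: list[PeakWindowSeq], path) -> None:
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f">{w.name}\n{w.sequence}\n")


def peaks_to_frame(peaks: list[Peak]):
    """Peak report table; positions 1-based for reporting."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "chrom": p.chrom,
                "strand": p.strand,
                "pos": p.end_pos + 1,
                "region": p.region.value,
                "x": p.x,
                "n": p.n,
                "dominance": p.dominance,
                "p_value": p.p_value,
                "excluded_mirna": p.excluded_mirna,
            }
            for p in peaks
        ],
        columns=[
            "chrom", "strand", "pos", "region", "x", "n",
            "dominance", "p_value", "excluded_mirna",
        ],
    )
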