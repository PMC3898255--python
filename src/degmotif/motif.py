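"""Position-anchored motif discovery, scanning, filtering and merging.

The motifs of interest here are short (6–8 nt), occur zero or once per input
sequence (ZOOPS), and — unlike generic motif discovery — sit at a *fixed
position* relative to the uncapped 5'-end of each 50-nt peak window. The
finder exploits exactly that: exact words are counted over all windows, words
supported by at least ``min_sites`` sequences are seeds, Hamming-distance-1
neighbours at compatible anchored offsets are merged into IUPAC consensi, and
each consensus is scored by a binomial E-value under a 0-order background
fitted to the input windows.

Offset frame (no zero, matching degradome reporting conventions): the
uncapped-end nucleotide of a 50-nt window is frame position +1; window
characters 1..25 (1-based) map to −25..−1, characters 26..50 to +1..+25.
A motif whose first base sits at frame +4 therefore starts 3 nt downstream of
the end — equivalently, the end lies at −3 in the motif's own frame.

The E-value here plays the role of an expected-false-discoveries score for
retention (threshold E < 1); it is an internal definition, not a re-creation
of any external motif program's statistic.
"""

from __future__ import annotations

import itertools
import random
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import binom

IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}
_SET_TO_CODE = {v: k for k, v in IUPAC.items()}

#: 1-based window position of the uncapped end in a 50-nt peak window
_END_WINDOW_POS = 26


def iupac_expand(consensus: str) -> list[frozenset[str]]:
    """Per-column nucleotide sets of an IUPAC consensus."""
    try:
        return [IUPAC[c] for c in consensus.upper()]
    except KeyError as exc:
        raise ValueError(f"illegal IUPAC character {exc.args[0]!r} in {consensus!r}")


def iupac_match(consensus: str, word: str) -> bool:
    """True iff every base of ``word`` lies in its consensus column set."""
    cols = iupac_expand(consensus)
    if len(word) != len(cols):
        raise ValueError(
            f"word length {len(word)} != consensus width {len(cols)}"
        )
    return all(b in col for b, col in zip(word.upper(), cols))


def iupac_from_sets(columns) -> str:
    return "".join(_SET_TO_CODE[frozenset(col)] for col in columns)


def matches_word(consensus: str, word: str) -> bool:
    """Length-checked variant used in tight loops (no validation)."""
    return all(b in IUPAC[c] for b, c in zip(word, consensus))


def window_pos_to_frame(pos1: int, end_pos: int = _END_WINDOW_POS) -> int:
    """Convert a 1-based window position to the no-zero end-anchored frame."""
    return pos1 - end_pos if pos1 < end_pos else pos1 - end_pos + 1


def frame_to_window_pos(offset: int, end_pos: int = _END_WINDOW_POS) -> int:
    if offset == 0:
        raise ValueError("the end-anchored frame has no position 0")
    return offset + end_pos if offset < 0 else offset + end_pos - 1


@dataclass
class MotifSite:
    seq_id: str | int
    offset: int  # frame offset of the motif's first base (no zero)
    word: str


@dataclass
class MotifSiteList:
    consensus: str
    sites: list[MotifSite] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sites)

    def offsets(self) -> list[int]:
        return [s.offset for s in self.sites]


@dataclass
class MotifModel:
    """An anchored motif: consensus, support, score and positional statistics."""

    consensus: str
    k: int  # sequences with a site (ZOOPS)
    n_input: int  # input sequences
    e_value: float
    modal_offset: int  # frame position of motif base 1 relative to the end (+1 = at the end)
    positional_dominance: float  # fraction of sites at modal_offset ±1
    sites: MotifSiteList = None
    provenance: str = ""

    @property
    def width(self) -> int:
        return len(self.consensus)

    @property
    def peak_offset_in_motif_frame(self) -> int:
        """Position of the uncapped end in the motif's own no-zero frame.

        A motif at end-frame +4 has the end 3 nt upstream of its first base,
        i.e. motif-frame −3.
        """
        m = self.modal_offset
        if m >= 1:
            return -(m - 1) if m > 1 else 1
        return -m + 1


@dataclass
class MotifGroup:
    members: list[MotifModel]
    representative: str
    #: per-member shift of the member's column 1 relative to the representative's
    member_shifts: list[int] = field(default_factory=list)


def scan_sequences(
    consensus: str,
    sequences: dict[str | int, str],
    zoops: bool = False,
    frame_anchor: int | None = _END_WINDOW_POS,
) -> MotifSiteList:
    """All match start offsets of a consensus per sequence.

    Offsets are reported in the end-anchored frame when ``frame_anchor`` is
    set (1-based window position of the anchor base), else as 1-based
    in-sequence positions. In ZOOPS mode one occurrence per sequence is kept:
    the one nearest the global modal offset, ties resolved upstream.
    """
    cols = iupac_expand(consensus)
    w = len(cols)
    raw: dict[str | int, list[int]] = {}
    for sid, seq in sequences.items():
        seq = seq.upper()
        hits = [
            j + 1
            for j in range(len(seq) - w + 1)
            if all(b in col for b, col in zip(seq[j : j + w], cols))
        ]
        if hits:
            raw[sid] = hits

    def to_frame(p1: int) -> int:
        return window_pos_to_frame(p1, frame_anchor) if frame_anchor else p1

    site_list = MotifSiteList(consensus)
    if not zoops:
        for sid, hits in raw.items():
            for p1 in hits:
                site_list.sites.append(
                    MotifSite(sid, to_frame(p1), sequences[sid][p1 - 1 : p1 - 1 + w].upper())
                )
        return site_list

    all_offsets = [to_frame(p) for hits in raw.values() for p in hits]
    modal = _modal_offset(all_offsets)
    for sid, hits in raw.items():
        best = min(hits, key=lambda p1: (abs(to_frame(p1) - modal), to_frame(p1)))
        site_list.sites.append(
            MotifSite(sid, to_frame(best), sequences[sid][best - 1 : best - 1 + w].upper())
        )
    return site_list


def _modal_offset(offsets) -> int:
    """Most frequent offset; ties → smallest |offset|, then negative first."""
    counts = Counter(offsets)
    return min(counts, key=lambda o: (-counts[o], abs(o), o > 0))


def positional_stats(sites: MotifSiteList) -> tuple[int, float]:
    """(modal offset, fraction of sites at modal ±1) of an anchored site list."""
    if not sites.sites:
        raise ValueError("empty site list")
    offsets = sites.offsets()
    modal = _modal_offset(offsets)
    near = sum(1 for o in offsets if abs(o - modal) <= 1)
    return modal, near / len(offsets)


def _background_freqs(sequences: list[str]) -> dict[str, float]:
    counts = Counter(itertools.chain.from_iterable(s.upper() for s in sequences))
    total = sum(counts[b] for b in "ACGT")
    if total == 0:
        return {b: 0.25 for b in "ACGT"}
    return {b: counts[b] / total for b in "ACGT"}


def consensus_evalue(
    consensus: str,
    k: int,
    n_seqs: int,
    seq_len: int,
    background: dict[str, float],
    n_words_tested: int,
) -> float:
    """Expected false discoveries: W · P(K ≥ k), K ~ Binomial(N, p₀).

    p₀ = 1 − (1 − p_word)^(L−w+1) is the per-sequence chance of at least one
    match of the consensus under a 0-order background; W (the number of
    distinct words examined at this width) is a Bonferroni-style factor.
    """
    cols = iupac_expand(consensus)
    p_word = 1.0
    for col in cols:
        p_word *= sum(background[b] for b in col)
    n_slots = max(seq_len - len(cols) + 1, 1)
    p0 = min(1.0, 1.0 - (1.0 - p_word) ** n_slots)
    if p0 >= 1.0:
        return float(n_words_tested)
    return float(n_words_tested) * float(binom.sf(k - 1, n_seqs, p0))


def discover_anchored(
    windows,
    widths: tuple[int, ...] = (6, 7, 8),
    min_sites: int = 5,
    background: dict[str, float] | None = None,
    hamming_radius: int = 1,
    max_models: int | None = 50,
) -> list[MotifModel]:
    """Discover position-anchored ZOOPS motifs in peak windows.

    ``windows`` is a list of 50-nt strings or objects with a ``sequence``
    attribute (PeakWindowSeq). Exact words of each width are counted over all
    windows; words present in ≥ ``min_sites`` distinct windows seed greedy
    Hamming-distance-``hamming_radius`` merges (restricted to words whose
    modal anchored offsets differ by ≤ 1) into IUPAC consensi. Each consensus
    is re-scanned in ZOOPS mode and scored; models are sorted by E-value.
    """
    seqs = {
        i: (w.sequence if hasattr(w, "sequence") else w).upper()
        for i, w in enumerate(windows)
    }
    n_seqs = len(seqs)
    if n_seqs < min_sites:
        raise ValueError(
            f"need at least min_sites={min_sites} windows, got {n_seqs}"
        )
    seq_len = max(len(s) for s in seqs.values())
    bg = background or _background_freqs(list(seqs.values()))

    models: list[MotifModel] = []
    for width in widths:
        word_seqs: dict[str, set[int]] = defaultdict(set)
        word_offsets: dict[str, list[int]] = defaultdict(list)
        for sid, seq in seqs.items():
            for j in range(len(seq) - width + 1):
                word = seq[j : j + width]
                if "N" in word:
                    continue
                word_seqs[word].add(sid)
                word_offsets[word].append(window_pos_to_frame(j + 1))
        n_words = len(word_seqs)
        cands = {w for w, s in word_seqs.items() if len(s) >= min_sites}
        order = sorted(cands, key=lambda w: (-len(word_seqs[w]), w))
        modal = {w: _modal_offset(word_offsets[w]) for w in order}
        used: set[str] = set()
        for seed in order:
            if seed in used:
                continue
            cluster = [seed]
            used.add(seed)
            for other in order:
                if other in used:
                    continue
                if (
                    _hamming(seed, other) <= hamming_radius
                    and abs(modal[other] - modal[seed]) <= 1
                ):
                    cluster.append(other)
                    used.add(other)
            consensus = iupac_from_sets(
                frozenset(w[i] for w in cluster) for i in range(width)
            )
            sites = scan_sequences(consensus, seqs, zoops=True)
            k = len(sites)
            if k < min_sites:
                continue
            modal_offset, dom = positional_stats(sites)
            e = consensus_evalue(consensus, k, n_seqs, seq_len, bg, n_words)
            models.append(
                MotifModel(consensus, k, n_seqs, e, modal_offset, dom, sites)
            )
    models.sort(key=lambda m: (m.e_value, -m.k, m.consensus))
    return models[:max_models] if max_models else models


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def filter_motifs(
    models: list[MotifModel], e_max: float = 1.0, dominance_min: float = 0.5
) -> list[MotifModel]:
    """Retain motifs with E < ``e_max`` and positional dominance ≥ ``dominance_min``."""
    return [
        m
        for m in models
        if m.e_value < e_max and m.positional_dominance >= dominance_min
    ]


def _best_alignment(a: str, b: str, min_overlap: int | None = None) -> tuple[float, int]:
    """(best similarity, shift of b relative to a) over ungapped alignments.

    Similarity = compatible columns / aligned columns, where a column pair is
    compatible when its IUPAC sets intersect. By default the shorter motif
    must be fully contained in the overlap (min_overlap = min width), which
    keeps short spurious end-overlaps from linking unrelated motifs.
    """
    if min_overlap is None:
        min_overlap = min(len(a), len(b))
    ca, cb = iupac_expand(a), iupac_expand(b)
    best, best_shift = -1.0, 0
    for shift in range(-(len(b) - min_overlap), len(a) - min_overlap + 1):
        pairs = [
            (ca[i], cb[i - shift])
            for i in range(max(0, shift), min(len(a), shift + len(b)))
        ]
        if len(pairs) < min_overlap:
            continue
        compat = sum(1 for x, y in pairs if x & y)
        sim = compat / len(pairs)
        if sim > best:
            best, best_shift = sim, shift
    return best, best_shift


def merge_motifs(
    models: list[MotifModel], similarity_min: float = 0.75, min_overlap: int | None = None
) -> list[MotifGroup]:
    """Greedy single-linkage grouping of motifs by consensus compatibility.

    Every input model ends up in exactly one group. The representative is the
    column-wise IUPAC union of the members aligned at their best shifts
    against the group's first (widest, most significant) member.
    """
    if not models:
        return []
    order = sorted(range(len(models)), key=lambda i: (models[i].e_value, -models[i].width))
    parent = list(range(len(models)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for ia, ib in itertools.combinations(order, 2):
        sim, _ = _best_alignment(models[ia].consensus, models[ib].consensus, min_overlap)
        if sim >= similarity_min:
            parent[find(ib)] = find(ia)

    clusters: dict[int, list[int]] = defaultdict(list)
    for i in order:
        clusters[find(i)].append(i)

    groups = []
    for root in sorted(clusters, key=lambda r: order.index(r)):
        idx = clusters[root]
        ref = models[idx[0]].consensus
        shifts = []
        cols: dict[int, set[str]] = defaultdict(set)
        for j, c in enumerate(iupac_expand(ref)):
            cols[j] |= set(c)
        member_shifts = []
        for i in idx:
            if models[i].consensus == ref:
                shift = 0
            else:
                _, shift = _best_alignment(ref, models[i].consensus)
            member_shifts.append(shift)
            for j, c in enumerate(iupac_expand(models[i].consensus)):
                cols[shift + j] |= set(c)
        lo, hi = min(cols), max(cols)
        rep = iupac_from_sets(frozenset(cols[j]) for j in range(lo, hi + 1))
        groups.append(MotifGroup([models[i] for i in idx], rep, member_shifts))
    return groups


def shuffle_motif(consensus: str, seed: int) -> str:
    """Seeded random non-identity anagram of a consensus (control motif)."""
    if len(consensus) < 2:
        raise ValueError("consensus must have width >= 2")
    if len(set(consensus)) == 1:
        raise ValueError(f"{consensus!r} has no non-identity anagram")
    rng = random.Random(seed)
    letters = list(consensus)
    while True:
        rng.shuffle(letters)
        out = "".join(letters)
        if out != consensus:
            return out


def import_sites_tsv(path: str | Path) -> MotifSiteList:
    """Bridge for externally discovered sites (e.g. a MEME run on exported windows).

    Expects a TSV with header columns sequence_id, offset, matched_word,
    consensus; offsets use the no-zero end-anchored frame.
    """
    path = Path(path)
    sites = MotifSiteList(consensus="")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sequence_id", "offset", "matched_word", "consensus"]
        if header != expected:
            raise ValueError(f"{path.name}: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path.name}:{lineno}: expected 4 columns")
            sid, off_s, word, consensus = parts
            try:
                offset = int(off_s)
            except ValueError:
                raise ValueError(f"{path.name}:{lineno}: offset {off_s!r} not an integer")
            if offset == 0:
                raise ValueError(f"{path.name}:{lineno}: frame has no position 0")
            if not sites.consensus:
                sites.consensus = consensus
            sites.sites.append(MotifSite(sid, offset, word))
    return sites


def motifs_to_frame(models: list[MotifModel]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "consensus": m.consensus,
                "width": m.width,
                "k": m.k,
                "N": m.n_input,
                "e_value": m.e_value,
                "modal_offset": m.modal_offset,
                "positional_dominance": m.positional_dominance,
                "provenance": m.provenance,
            }
            for m in models
        ],
        columns=[
            "consensus", "width", "k", "N", "e_value",
            "modal_offset", "positional_dominance", "provenance",
        ],
    )
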