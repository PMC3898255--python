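"""End-to-end discovery pipeline orchestration.

Runs the full flow — collapse reads → classify → call peaks → exclude miRNA
sites → cap at the top 1000 per region → extract 50-nt windows → discover
anchored motifs → filter by E-value and positional dominance → MORPH each
retained motif — and writes per-stage TSV/FASTA outputs plus a run log with
per-filter counts. Every output carries the tool version and a hash of the
configuration, and reruns on identical inputs are bit-identical for TSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from degmotif import __version__
from degmotif.core_io import RegionLabel, read_end_bed, read_fasta, read_gff3
from degmotif.morph import (
    anchors_from_motif,
    build_matrix,
    matrix_to_frame,
    render_heatmap,
    summarize,
    ward_cluster,
)
from degmotif.motif import (
    discover_anchored,
    filter_motifs,
    merge_motifs,
    motifs_to_frame,
)
from degmotif.peakcall import (
    PeakTestParams,
    call_peaks,
    extract_windows,
    filter_mirna_sites,
    peaks_to_frame,
    read_site_bed,
    select_top,
    write_windows_fasta,
)

logger = logging.getLogger("degmotif")

ALL_REGIONS = (
    RegionLabel.FIVE_UTR,
    RegionLabel.CDS,
    RegionLabel.THREE_UTR,
    RegionLabel.INTRON,
    RegionLabel.IGR,
)


@dataclass
class PipelineConfig:
    genome: str
    gff: str
    reads: str
    out_dir: str
    mirna_sites: str | None = None
    bed_score: str = "count"  # BED score-column dialect
    drop_multi: bool = False
    regions: tuple[RegionLabel, ...] = ALL_REGIONS
    params: PeakTestParams = field(default_factory=PeakTestParams)
    motif_widths: tuple[int, ...] = (6, 7, 8)
    min_sites: int = 5
    e_max: float = 1.0
    motif_dominance_min: float = 0.5
    merge_similarity_min: float = 0.75
    morph_halfwidth: int = 10
    morph_min_total: int = 5
    morph_filter_on: bool = True
    ward_variant: str = "D2"
    render: bool = True
    seed: int = 1

    def validate(self) -> None:
        for label, p in (("genome", self.genome), ("gff", self.gff), ("reads", self.reads)):
            if not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")
        if self.mirna_sites and not Path(self.mirna_sites).exists():
            raise FileNotFoundError(f"mirna_sites path does not exist: {self.mirna_sites}")

    def hash(self) -> str:
        payload = asdict(self)
        payload["regions"] = [r.value for r in self.regions]
        payload.pop("out_dir", None)  # purely an output location
        payload.pop("render", None)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        if "regions" in raw:
            raw["regions"] = tuple(RegionLabel(r) for r in raw["regions"])
        if "params" in raw and isinstance(raw["params"], dict):
            raw["params"] = PeakTestParams(**raw["params"])
        return cls(**raw)


@dataclass
class RegionResult:
    region: RegionLabel
    peaks: list
    kept_peaks: list  # after miRNA exclusion and top-k
    windows: list
    models: list
    retained_models: list
    morph_summaries: dict  # consensus -> MorphSummary


@dataclass
class RunResult:
    out_dir: Path
    config: PipelineConfig
    regions: dict[RegionLabel, RegionResult]
    groups: list
    counts: dict


def _provenance(config: PipelineConfig) -> str:
    return f"# degmotif {__version__} config={config.hash()}\n"


def _write_tsv(df, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def run_discovery(config: PipelineConfig) -> RunResult:
    """Execute the full pipeline; returns in-memory results and writes files."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> RunResult:
    logger.info("degmotif %s config=%s", __version__, config.hash())
    genome = read_fasta(config.genome)
    annotation = read_gff3(config.gff)
    table = read_end_bed(
        config.reads, score=config.bed_score, drop_multi=config.drop_multi, genome=genome
    )
    logger.info("input: %d distinct ends, %d total reads", len(table), table.total)
    exclusion = read_site_bed(config.mirna_sites) if config.mirna_sites else []

    peaks_by_region = call_peaks(table, annotation, config.params)
    counts: dict = {"candidates": len(table)}
    all_rows = []
    region_results: dict[RegionLabel, RegionResult] = {}
    all_retained_models = []

    for region in config.regions:
        peaks = peaks_by_region.get(region, [])
        peaks = filter_mirna_sites(peaks, exclusion, config.params.mirna_tolerance)
        n_excluded = sum(p.excluded_mirna for p in peaks)
        kept = select_top([p for p in peaks if not p.excluded_mirna], config.params)
        logger.info(
            "region %s: %d significant peaks, %d miRNA-excluded, %d kept (top %d)",
            region.value, len(peaks), n_excluded, len(kept), config.params.top_k,
        )
        counts[f"{region.value}/significant"] = len(peaks)
        counts[f"{region.value}/mirna_excluded"] = n_excluded
        counts[f"{region.value}/kept"] = len(kept)
        all_rows.append(peaks_to_frame(peaks))

        windows = extract_windows(kept, genome) if kept else []
        if windows:
            write_windows_fasta(windows, out / f"windows_{region.value}.fa")
        models, retained = [], []
        if len(windows) >= config.min_sites:
            models = discover_anchored(
                windows, widths=config.motif_widths, min_sites=config.min_sites
            )
            retained = filter_motifs(models, config.e_max, config.motif_dominance_min)
            for m in models:
                m.provenance = region.value
        logger.info(
            "region %s: %d motif models, %d pass E<%g and dominance>=%g",
            region.value, len(models), len(retained), config.e_max,
            config.motif_dominance_min,
        )
        counts[f"{region.value}/motifs"] = len(models)
        counts[f"{region.value}/motifs_retained"] = len(retained)

        summaries = {}
        for model in retained:
            anchors = anchors_from_motif(annotation, genome, model.consensus, region)
            if not anchors.anchors:
                continue
            matrix = build_matrix(
                anchors, table,
                halfwidth=config.morph_halfwidth,
                min_total=config.morph_min_total,
                filter_on=config.morph_filter_on,
            )
            if matrix.n_retained:
                ward_cluster(matrix, variant=config.ward_variant)
            summaries[model.consensus] = summarize(matrix, allow_empty=True)
            tag = f"{region.value}_{model.consensus}"
            _write_tsv(matrix_to_frame(matrix), out / f"morph_{tag}.tsv", config)
            if config.render and matrix.n_retained:
                render_heatmap(
                    matrix, out / f"morph_{tag}.png",
                    motif_width=model.width, title=model.consensus,
                )
        region_results[region] = RegionResult(
            region, peaks, kept, windows, models, retained, summaries
        )
        all_retained_models.extend(retained)

    import pandas as pd

    non_empty = [df for df in all_rows if not df.empty]
    peaks_df = (
        pd.concat(non_empty, ignore_index=True) if non_empty else peaks_to_frame([])
    )
    _write_tsv(peaks_df, out / "peaks.tsv", config)
    all_models = [m for r in region_results.values() for m in r.models]
    _write_tsv(motifs_to_frame(all_models), out / "motifs.tsv", config)
    _write_tsv(motifs_to_frame(all_retained_models), out / "motifs_retained.tsv", config)

    groups = merge_motifs(all_retained_models, config.merge_similarity_min)
    groups_df = pd.DataFrame(
        [
            {
                "group": gi,
                "representative": g.representative,
                "member": m.consensus,
                "region": m.provenance,
                "modal_offset": m.modal_offset,
                "e_value": m.e_value,
            }
            for gi, g in enumerate(groups)
            for m in g.members
        ],
        columns=["group", "representative", "member", "region", "modal_offset", "e_value"],
    )
    _write_tsv(groups_df, out / "groups.tsv", config)
    logger.info("%d motif groups from %d retained models", len(groups), len(all_retained_models))
    return RunResult(out, config, region_results, groups, counts)
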