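"""End-to-end orchestration: genotyping -> events -> classify -> statistics.

The pipeline consumes a marker map, per-site allele counts and a sample
sheet, and emits event tables, per-meiosis summaries and a QC report,
plus a manifest recording the configuration hash and seed so identical
inputs reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .classify import HotspotTrack, classify_all, qc_filter
from .events import call_events, segment_chromosome
from .genome import GenomeModel, yeast_genome
from .genotyping import (
    CallerConfig,
    assemble_octad,
    build_mocktad,
    calls_to_matrices,
    duplicate_tetrad,
    phase_with_colony,
)
from .matrix import HET, StrandMatrix
from .meiostats import summarize_meiosis

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "analyze_matrices"]


@dataclass
class PipelineConfig:
    marker_map: str
    site_counts: str
    sample_sheet: str
    output_dir: str
    genome_table: str | None = None      # default: S. cerevisiae R64
    hotspot_bed: str | None = None
    mode: str = "octad"                  # octad | tetrad | mocktad
    caller: CallerConfig = field(default_factory=CallerConfig)
    min_gap_bp: int = 1500
    seed: int = 0
    genotype_label: str = ""

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        caller = CallerConfig(**raw.pop("caller", {}))
        return cls(caller=caller, **raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def analyze_matrices(
    matrices: dict[str, StrandMatrix],
    mode: str = "octad",
    hotspots: HotspotTrack | None = None,
    min_gap_bp: int = 1500,
):
    """Segment, call and classify all events of one meiosis."""
    events = []
    for chrom in matrices:
        sm = matrices[chrom]
        seg = segment_chromosome(sm)
        evs = call_events(seg, min_gap_bp=min_gap_bp)
        classify_all(evs, mode=mode, hotspots=hotspots,
                     polarity_known=sm.polarity_known)
        events.extend(evs)
    return events


def _build_meiosis_matrices(
    counts: pd.DataFrame,
    marker_map: pd.DataFrame,
    sheet: pd.DataFrame,
    mode: str,
    cfg: CallerConfig,
) -> tuple[dict[str, StrandMatrix], dict[str, np.ndarray]]:
    """Genotype one meiosis and assemble its strand matrices.

    Returns the per-chromosome matrices and the per-chromosome heteroduplex
    fractions per spore sample (for the disomy QC check).
    """
    role = "strand" if mode == "octad" else "colony"
    members = sheet[sheet["role"] == role].sort_values("spore")
    samples = members["sample"].tolist()
    reseq = sheet[sheet["role"] == "reseq"]
    all_samples = samples + reseq["sample"].tolist()
    calls = calls_to_matrices(
        counts[counts["sample"].isin(all_samples)], marker_map, all_samples, cfg
    )
    matrices: dict[str, StrandMatrix] = {}
    het_fracs: dict[str, np.ndarray] = {}
    n_members = len(samples)
    for chrom, (pos, mat) in calls.items():
        member_calls = mat[:n_members]
        het_fracs[chrom] = (member_calls == HET).mean(axis=1) if mat.shape[1] else np.zeros(n_members)
        if mode == "octad":
            matrices[chrom] = assemble_octad(member_calls, pos, chrom)
        elif mode == "tetrad":
            matrices[chrom] = duplicate_tetrad(member_calls, pos, chrom)
        else:
            sm = build_mocktad(member_calls, pos, chrom, cfg)
            for i, (_, row) in enumerate(reseq.iterrows()):
                spore = int(row["spore"])
                colony = mat[n_members + i]
                keep = np.isin(pos, sm.positions)
                sm, unresolved = phase_with_colony(sm, spore, colony[keep])
                if unresolved:
                    logger.info(
                        "%s spore %d: %d heteroduplex markers left unphased",
                        chrom, spore, unresolved,
                    )
            matrices[chrom] = sm
    return matrices, het_fracs


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the post-alignment pipeline and write all outputs.

    Stages: genotype calling, octad/mocktad assembly, segmentation and
    event calling, classification, cross-meiosis QC, per-meiosis
    summaries.  Every output is deterministic given config + inputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    marker_map = mio.read_marker_map(config.marker_map)
    counts = mio.read_site_counts(config.site_counts)
    sheet = mio.read_sample_sheet(config.sample_sheet)
    mio.validate_sample_sheet(sheet, "octad" if config.mode == "octad" else "tetrad")
    genome = (
        mio.read_genome_table(config.genome_table)
        if config.genome_table
        else yeast_genome()
    )
    hotspots = None
    if config.hotspot_bed:
        hotspots = HotspotTrack.from_frame(mio.read_bed(config.hotspot_bed))

    events_by_meiosis: dict[str, list] = {}
    het_by_meiosis: dict[tuple, np.ndarray] = {}
    for mid, sub in sheet.groupby("meiosis", sort=False):
        logger.info("meiosis %s: genotyping", mid)
        matrices, het_fracs = _build_meiosis_matrices(
            counts, marker_map, sub, config.mode, config.caller
        )
        events = analyze_matrices(
            matrices, mode=config.mode, hotspots=hotspots,
            min_gap_bp=config.min_gap_bp,
        )
        logger.info("meiosis %s: %d events called", mid, len(events))
        events_by_meiosis[mid] = events
        for chrom, fr in het_fracs.items():
            het_by_meiosis[(mid, chrom)] = fr

    filtered, qc_report = qc_filter(events_by_meiosis, het_fractions=het_by_meiosis)

    event_frames = []
    summaries = []
    for mid, events in filtered.items():
        event_frames.append(mio.events_to_frame(events, meiosis_id=str(mid)))
        s = summarize_meiosis(str(mid), events, genome, genotype=config.genotype_label)
        summaries.append(s)
    events_df = (
        pd.concat(event_frames, ignore_index=True) if event_frames else pd.DataFrame()
    )
    summary_df = pd.DataFrame(
        [
            {
                "meiosis": s.meiosis_id,
                "genotype": s.genotype,
                "co_count": s.co_count,
                "nco_count": s.nco_count,
                "complex_count": s.complex_count,
                "type_u_count": s.type_u_count,
                "trans_dsb_count": s.trans_dsb_count,
                "n_nonexchange_zero_co": len(s.nonexchange_zero_co),
                "n_nonexchange_zero_co_nco": len(s.nonexchange_zero_co_nco),
                "premeiotic_suspect": s.meiosis_id in {str(m) for m in qc_report.flagged_meioses},
                **{f"n_{k}": v for k, v in s.multi_dsb_counts.items()},
            }
            for s in summaries
        ]
    )
    icd_df = pd.concat(
        [
            pd.DataFrame({"meiosis": s.meiosis_id, "icd_bp": s.icds})
            for s in summaries
        ],
        ignore_index=True,
    ) if summaries else pd.DataFrame()

    events_df.to_csv(outdir / "events.tsv", sep="\t", index=False)
    summary_df.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    icd_df.to_csv(outdir / "icds.tsv", sep="\t", index=False)
    qc_report.dropped.to_csv(outdir / "qc_dropped.tsv", sep="\t", index=False)

    hashed = {k: v for k, v in config.to_dict().items() if k != "output_dir"}
    cfg_yaml = yaml.safe_dump(hashed, sort_keys=True)
    manifest = {
        "package": "meiomap",
        "version": _version(),
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "n_meioses": len(filtered),
        "n_events": int(len(events_df)),
        "premeiotic_suspect": sorted(str(m) for m in qc_report.flagged_meioses),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "events": events_df,
        "summaries": summaries,
        "summary_table": summary_df,
        "qc": qc_report,
        "manifest": manifest,
    }


def _version() -> str:
    from importlib.metadata import version

    try:
        return version("meiomap")
    except Exception:
        return "unknown"
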