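"""Tab-separated and BED interfaces.

Conventions: marker and matrix coordinates are 1-based inclusive
throughout the package; BED files are 0-based half-open on disk and are
converted at this boundary.  All TSV readers are gzip-tolerant (pandas
infers compression from the filename).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .matrix import HET, MISSING, StrandMatrix

__all__ = [
    "read_marker_map", "write_marker_map",
    "read_site_counts", "write_site_counts",
    "read_genome_table", "write_genome_table",
    "read_bed", "write_bed",
    "read_sample_sheet", "validate_sample_sheet",
    "write_matrix", "read_matrix",
    "events_to_frame", "write_events",
    "events_to_bed",
]

_MAP_COLS = ["chrom", "pos", "allele_a", "allele_b", "kind"]
_COUNT_COLS = ["sample", "chrom", "pos", "n_ref", "n_var", "n_other", "depth"]


def _read_tsv(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_marker_map(path) -> pd.DataFrame:
    df = _read_tsv(path, _MAP_COLS)
    bad = ~df["kind"].isin(["SNP", "insertion", "deletion"])
    if bad.any():
        lines = (df.index[bad] + 2).tolist()[:5]
        raise ValueError(f"{path}: invalid marker kind at line(s) {lines}")
    for chrom, sub in df.groupby("chrom"):
        if np.any(np.diff(sub["pos"].to_numpy()) <= 0):
            raise ValueError(f"{path}: positions not strictly increasing on {chrom}")
    return df


def write_marker_map(df: pd.DataFrame, path) -> None:
    df[_MAP_COLS].to_csv(path, sep="\t", index=False)


def read_site_counts(path) -> pd.DataFrame:
    return _read_tsv(path, _COUNT_COLS)


def write_site_counts(df: pd.DataFrame, path) -> None:
    df[_COUNT_COLS].to_csv(path, sep="\t", index=False)


def read_genome_table(path) -> GenomeModel:
    """Genome TSV: chrom, length[, centromere]."""
    df = _read_tsv(path, ["chrom", "length"])
    cen = tuple(df["centromere"].astype(int)) if "centromere" in df.columns else ()
    return GenomeModel(
        names=tuple(df["chrom"]), lengths=tuple(df["length"].astype(int)),
        centromeres=cen,
    )


def write_genome_table(genome: GenomeModel, path) -> None:
    df = pd.DataFrame({"chrom": genome.names, "length": genome.lengths})
    if genome.centromeres:
        df["centromere"] = genome.centromeres
    df.to_csv(path, sep="\t", index=False)


def read_bed(path, internal: bool = False) -> pd.DataFrame:
    """Read a BED3(+1) file; optionally convert to 1-based inclusive coords."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "strength"][: 4],
    )
    if df["end"].isna().all():
        raise ValueError(f"{path}: not a BED file (fewer than 3 columns)")
    if "strength" in df.columns and df["strength"].isna().all():
        df = df.drop(columns=["strength"])
    bad = df["end"] <= df["start"]
    if bad.any():
        lines = (df.index[bad] + 1).tolist()[:5]
        raise ValueError(f"{path}: end <= start at line(s) {lines}")
    if internal:
        df = df.assign(start=df["start"] + 1)   # [start+1, end] inclusive
    return df


def write_bed(df: pd.DataFrame, path, from_internal: bool = False) -> None:
    """Write intervals to BED; 1-based inclusive input when ``from_internal``."""
    out = df.copy()
    if from_internal:
        out["start"] = out["start"] - 1
    if (out["end"] <= out["start"]).any():
        raise ValueError("intervals must satisfy start < end after conversion")
    cols = [c for c in ["chrom", "start", "end", "strength"] if c in out.columns]
    out[cols].to_csv(path, sep="\t", index=False, header=False)


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: sample, meiosis, spore, role.

    role is "strand" (octad member; spore counts strands 0-7 in
    mother/daughter order), "colony" (tetrad whole-colony sample, spore
    0-3) or "reseq" (restreaked single-colony sample used for phasing,
    spore 0-3).
    """
    return _read_tsv(path, ["sample", "meiosis", "spore", "role"])


def validate_sample_sheet(sheet: pd.DataFrame, mode: str) -> None:
    need = 8 if mode == "octad" else 4
    role = "strand" if mode == "octad" else "colony"
    for mid, sub in sheet.groupby("meiosis"):
        n = int((sub["role"] == role).sum())
        if n != need:
            raise ValueError(
                f"meiosis {mid}: {mode} mode requires {need} {role} samples, found {n}"
            )


_GENO_CODE = {1: "1", 0: "0", HET: "H", MISSING: "NA"}
_GENO_DECODE = {"1": 1, "0": 0, "H": HET, "NA": MISSING}


def write_matrix(matrices: dict[str, StrandMatrix], path) -> None:
    """Genotype-matrix TSV: one row per marker, eight strand columns."""
    frames = []
    for chrom, sm in matrices.items():
        d = {"chrom": chrom, "pos": sm.positions}
        for r in range(8):
            d[f"strand{r}"] = [_GENO_CODE[int(v)] for v in sm.geno[r]]
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_matrix(path) -> dict[str, StrandMatrix]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = [c for c in ["chrom", "pos"] + [f"strand{r}" for r in range(8)]
               if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = {}
    for chrom, sub in df.groupby("chrom", sort=False):
        geno = np.array(
            [[_GENO_DECODE[str(v)] for v in sub[f"strand{r}"]] for r in range(8)],
            dtype=np.int8,
        )
        out[chrom] = StrandMatrix(
            chrom=chrom, positions=sub["pos"].to_numpy(np.int64), geno=geno
        )
    return out


def _midlength(ev) -> float:
    from .meiostats import event_midlength

    return event_midlength(ev)


def events_to_frame(events, meiosis_id: str = "") -> pd.DataFrame:
    """Flat event table (one row per event) for TSV export."""
    rows = []
    for ev in events:
        cat = ev.category
        rows.append(
            {
                "meiosis": meiosis_id,
                "chrom": ev.chrom,
                "start": ev.start_pos,
                "end": ev.end_pos,
                "n_markers": ev.n_markers,
                "co_count": ev.co_count,
                "nco_count": ev.nco_count,
                "type_u": ev.type_u,
                "complex": ev.complex_flag,
                "chromatids": ",".join(map(str, sorted(set(ev.changed_chromatids) | set(ev.nco_runs)))),
                "pattern": ev.pattern_string(),
                "mid_length": "" if ev.type_u else _midlength(ev),
                "multi_dsb": cat.multi_dsb if cat else "",
                "trans_dsb": "" if cat is None or cat.trans_dsb is None else cat.trans_dsb,
                "nco_class": cat.nco_class if cat else "",
                "co_class": cat.co_class if cat else "",
                "template_switch": ";".join(sorted(cat.template_switch)) if cat else "",
                "qc_flags": ";".join(sorted(cat.qc_flags)) if cat else "",
            }
        )
    return pd.DataFrame(rows)


def write_events(events, path, meiosis_id: str = "") -> None:
    events_to_frame(events, meiosis_id).to_csv(path, sep="\t", index=False)


def events_to_bed(events, path) -> None:
    """Export event spans as BED (0-based half-open)."""
    rows = [
        {"chrom": ev.chrom, "start": max(0, ev.start_pos - 1), "end": ev.end_pos}
        for ev in events
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)
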