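"""Readers and writers for the pipeline's external formats.

Formats
-------
* Probe table: TSV with header columns Chromosome, Position, Log2Ratio, BAF
  (OncoScan-style text export; the mapping is configurable).
* Segments: SEG — tab-separated Sample, Chromosome, Start, End, Num_Probes,
  Segment_Mean and an optional Segment_mBAF column. 1-based inclusive.
* Clinical: CSV with patient_id, efs_days, efs_event, os_days, os_event and
  optional cc, cc_class, coo and covariates.
* CC report: JSON with stable key order.

Every dropped row is counted and logged — never silent.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import (
    AUTOSOMES,
    CLINICAL_REQUIRED,
    CohortTable,
    ProbeSet,
    Segment,
    SegmentSet,
)

logger = logging.getLogger(__name__)

DEFAULT_PROBE_COLUMNS = {
    "chrom": "Chromosome",
    "pos": "Position",
    "log2r": "Log2Ratio",
    "baf": "BAF",
}

SEG_COLUMNS = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]


def _normalize_chrom(values: pd.Series) -> pd.Series:
    return values.astype(str).str.replace("^chr", "", regex=True)


def read_probe_table(
    path: str | Path,
    dialect: str = "oncoscan_tsv",
    column_map: dict[str, str] | None = None,
    sample_id: str | None = None,
) -> ProbeSet:
    """Read a probe-level TSV into a validated :class:`ProbeSet`.

    Non-autosomal rows and rows with missing or out-of-range BAF/log2R are
    dropped with a logged count.
    """
    if dialect != "oncoscan_tsv":
        raise ValueError(f"unknown dialect {dialect!r}")
    colmap = dict(DEFAULT_PROBE_COLUMNS, **(column_map or {}))
    try:
        raw = pd.read_csv(path, sep="\t")
    except OSError as exc:
        raise OSError(f"cannot read probe table {path}: {exc}") from exc
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise ValueError(
            f"probe table {path} lacks expected column(s) {missing}; found {list(raw.columns)}"
        )
    df = raw.rename(columns={v: k for k, v in colmap.items()})[["chrom", "pos", "log2r", "baf"]]
    df["chrom"] = _normalize_chrom(df["chrom"])
    n0 = len(df)

    autosomal = df["chrom"].isin(AUTOSOMES)
    if (n_drop := int((~autosomal).sum())):
        logger.info("dropped %d non-autosomal probe rows", n_drop)
    df = df[autosomal]

    valid = (
        df["baf"].notna()
        & (df["baf"] >= 0)
        & (df["baf"] <= 1)
        & df["log2r"].notna()
        & np.isfinite(df["log2r"])
    )
    if (n_drop := int((~valid).sum())):
        logger.info("dropped %d probe rows with missing/invalid BAF or log2R", n_drop)
    df = df[valid]

    df = df.drop_duplicates(subset=["chrom", "pos"], keep="first")
    if len(df) == 0:
        raise ValueError(f"probe table {path}: no usable rows out of {n0}")
    return ProbeSet(df.reset_index(drop=True), sample_id=sample_id or Path(path).stem)


def write_probe_table(probes: ProbeSet, path: str | Path) -> None:
    """Write a :class:`ProbeSet` in the default TSV dialect (6-decimal floats)."""
    out = probes.df.rename(
        columns={"chrom": "Chromosome", "pos": "Position", "log2r": "Log2Ratio", "baf": "BAF"}
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_seg(path: str | Path, genome_bp: int | None = None) -> SegmentSet:
    """Read a SEG file (optionally with a Segment_mBAF column).

    Segments lacking mBAF are BAF-uninformative (``med_mbaf=None``).
    ``genome_bp`` defaults to the summed segment span.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except OSError as exc:
        raise OSError(f"cannot read SEG file {path}: {exc}") from exc
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SEG file {path} lacks column(s) {missing}")
    has_mbaf = "Segment_mBAF" in df.columns
    segments = []
    for row in df.itertuples(index=False):
        mbaf = getattr(row, "Segment_mBAF", None) if has_mbaf else None
        if mbaf is not None and (isinstance(mbaf, float) and np.isnan(mbaf)):
            mbaf = None
        segments.append(
            Segment(
                chrom=str(row.Chromosome).removeprefix("chr"),
                start_bp=int(row.Start),
                end_bp=int(row.End),
                n_probes=int(row.Num_Probes),
                med_log2r=float(row.Segment_Mean),
                med_mbaf=None if mbaf is None else float(mbaf),
            )
        )
    if genome_bp is None:
        genome_bp = sum(s.length_bp for s in segments)
    sample = str(df["Sample"].iloc[0]) if len(df) else "sample"
    return SegmentSet(segments, genome_bp=genome_bp, sample_id=sample)


def write_seg(segset: SegmentSet, path: str | Path) -> None:
    """Write SEG including the Segment_mBAF column (empty when absent)."""
    rows = [
        {
            "Sample": segset.sample_id,
            "Chromosome": s.chrom,
            "Start": s.start_bp,
            "End": s.end_bp,
            "Num_Probes": s.n_probes,
            "Segment_Mean": f"{s.med_log2r:.6f}",
            "Segment_mBAF": "" if s.med_mbaf is None else f"{s.med_mbaf:.6f}",
        }
        for s in segset.segments
    ]
    pd.DataFrame(rows, columns=SEG_COLUMNS + ["Segment_mBAF"]).to_csv(path, sep="\t", index=False)


def write_cc_report(result, path: str | Path) -> None:
    """Serialize a :class:`~clonecomp.cc.CCResult` as JSON with stable key order."""
    doc = {
        "tool": "clonecomp",
        "version": __version__,
        "sample_id": result.sample_id,
        "cc": result.cc,
        "classification": result.classification,
        "genome_bp": result.genome_bp,
        "footprint_denominator": "analyzed autosomal span (probe-covered)",
        "clusters": [
            {
                "centroid_f": round(c.centroid_f, 6),
                "footprint_bp": c.footprint_bp,
                "footprint_fraction": round(c.footprint_fraction, 8),
                "passes_footprint": c.passes_footprint,
                "members": [
                    {
                        "chrom": m.segment.chrom,
                        "start_bp": m.segment.start_bp,
                        "end_bp": m.segment.end_bp,
                        "n_total": m.state.n_total,
                        "n_minor": m.state.n_minor,
                        "f": round(m.f, 6),
                        "residual": round(m.residual, 8),
                    }
                    for m in c.members
                ],
            }
            for c in result.clusters
        ],
        "config": result.config.to_dict(),
    }
    try:
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=False)
            fh.write("\n")
    except OSError as exc:
        raise OSError(f"cannot write CC report {path}: {exc}") from exc


def read_clinical_csv(path: str | Path, mono_if_cc_le: int = 0) -> CohortTable:
    """Read the clinical CSV into a validated :class:`CohortTable`.

    Missing categorical values are coded ``"NA"``; a negative follow-up
    time is a hard error (garbage in survival times invalidates every
    downstream estimate).
    """
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"clinical file {path} lacks required column(s): {missing}")
    for col in df.columns:
        if df[col].dtype == object:
            df[col] = df[col].fillna("NA")
    return CohortTable(df, mono_if_cc_le=mono_if_cc_le)


def write_clinical_csv(cohort: CohortTable, path: str | Path) -> None:
    cohort.df.to_csv(path, index=False)
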