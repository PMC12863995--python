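"""Core in-memory containers shared across the pipeline.

Coordinates are 1-based inclusive throughout (SEG convention). Only the 22
autosomes are analyzed: BAF expectations on sex chromosomes depend on sex,
which the model does not handle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES: tuple[str, ...] = tuple(str(c) for c in range(1, 23))

PROBE_COLUMNS = ("chrom", "pos", "log2r", "baf")


def _chrom_order(chrom: pd.Series) -> pd.Series:
    return chrom.map({c: i for i, c in enumerate(AUTOSOMES)})


@dataclass
class ProbeSet:
    """Per-locus allele-specific array observations for one sample.

    ``df`` has columns chrom ("1".."22"), pos (1-based bp), log2r, baf;
    rows sorted by (chrom, pos) with no duplicate locus.
    """

    df: pd.DataFrame
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        missing = [c for c in PROBE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"probe table missing columns: {missing}")
        self.df = self.df.loc[:, list(PROBE_COLUMNS)].copy()
        self.df["chrom"] = self.df["chrom"].astype(str)
        self.df["pos"] = self.df["pos"].astype(np.int64)
        self.validate()

    def validate(self) -> None:
        df = self.df
        bad_chrom = ~df["chrom"].isin(AUTOSOMES)
        if bad_chrom.any():
            raise ValueError(
                f"non-autosomal chromosomes present: {sorted(df.loc[bad_chrom, 'chrom'].unique())}"
            )
        if ((df["baf"] < 0) | (df["baf"] > 1) | df["baf"].isna()).any():
            raise ValueError("BAF outside [0, 1] or missing")
        if not np.isfinite(df["log2r"]).all():
            raise ValueError("non-finite log2R values")
        order = np.lexsort((df["pos"].to_numpy(), _chrom_order(df["chrom"]).to_numpy()))
        if not np.array_equal(order, np.arange(len(df))):
            self.df = df.iloc[order].reset_index(drop=True)
        if self.df.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError("duplicate (chrom, pos) loci")

    @property
    def records(self) -> list[tuple[str, int, float, float]]:
        return list(self.df.itertuples(index=False, name=None))

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class Segment:
    """Genomic interval with summary signals (1-based inclusive)."""

    chrom: str
    start_bp: int
    end_bp: int
    n_probes: int
    med_log2r: float
    med_mbaf: float | None = None  # absent when too few informative probes

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ValueError(f"segment end {self.end_bp} < start {self.start_bp}")
        if self.med_mbaf is not None and not (0.5 - 1e-9 <= self.med_mbaf <= 1 + 1e-9):
            raise ValueError(f"med_mbaf {self.med_mbaf} outside [0.5, 1]")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class SegmentSet:
    """Non-overlapping segments of one sample plus the analyzed genome span."""

    segments: list[Segment]
    genome_bp: int
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.genome_bp <= 0:
            raise ValueError("genome_bp must be positive")
        by_chrom: dict[str, list[Segment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        offenders = []
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start_bp)
            for a, b in zip(segs, segs[1:]):
                if b.start_bp <= a.end_bp:
                    offenders.append((chrom, (a.start_bp, a.end_bp), (b.start_bp, b.end_bp)))
        if offenders:
            raise ValueError(f"overlapping segments: {offenders}")
        total = sum(s.length_bp for s in self.segments)
        if total > self.genome_bp:
            raise ValueError("segments span more than genome_bp")

    def __len__(self) -> int:
        return len(self.segments)


CLINICAL_REQUIRED = ("patient_id", "efs_days", "efs_event", "os_days", "os_event")


@dataclass
class CohortTable:
    """Per-patient clinical + CC records; one row per patient."""

    df: pd.DataFrame
    mono_if_cc_le: int = 0

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_REQUIRED if c not in self.df.columns]
        if missing:
            raise ValueError(f"clinical table missing required column(s): {missing}")
        df = self.df
        for col in ("efs_days", "os_days"):
            if (df[col] < 0).any():
                bad = df.index[df[col] < 0].tolist()
                raise ValueError(f"negative {col} at rows {bad}")
        for col in ("efs_event", "os_event"):
            if not df[col].isin([0, 1]).all():
                raise ValueError(f"{col} must be 0/1")
        if "cc" in df.columns and "cc_class" in df.columns:
            has_cc = df["cc"].notna()
            expect = np.where(df.loc[has_cc, "cc"] <= self.mono_if_cc_le, "Mono", "Poly")
            got = df.loc[has_cc, "cc_class"].astype(str).to_numpy()
            if not np.array_equal(expect, got):
                raise ValueError("cc_class inconsistent with cc under the Mono rule")

    def __len__(self) -> int:
        return len(self.df)
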