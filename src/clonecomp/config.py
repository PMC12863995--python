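"""Run configuration: every tunable of the CC pipeline in one place.

All thresholds that govern segmentation, aberrance calling, copy-state
fitting, fraction clustering and the clone-calling footprint are exposed
here so that sensitivity analyses (e.g. lowering the footprint from 1% to
0.5%) are one-line config changes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Tunable parameters of the clonal-composition pipeline.

    Parameters
    ----------
    footprint_fraction : float
        Minimum fraction of the analyzed autosomal genome that a
        cellular-fraction cluster must span to be counted as a clone
        (the clone-calling footprint). Default 0.01 (1%); 0.005 is the
        sensitivity setting.
    delta_f : float
        Cluster-merge tolerance on the cellular-fraction axis: a segment
        joins the running cluster when its fitted fraction is within
        ``delta_f`` of the cluster's length-weighted centroid.
    tau_log2r : float
        Absolute log2-ratio deviation above which a segment is called
        copy-number aberrant.
    tau_mbaf : float
        Mirrored-BAF level at or above which a segment is called
        allelically aberrant.
    min_probes : int
        Minimum number of member probes for an emitted segment.
    max_total_copy : int
        Largest total copy number in the fitted state grid.
    mono_if_cc_le : int
        Classification rule: Mono when ``cc <= mono_if_cc_le``.
    informative_baf_window : tuple of float
        Open BAF interval treated as germline-heterozygous (informative)
        in the absence of a matched normal.
    seg_penalty : float
        BIC-style penalty multiplier lambda for accepting a change-point
        split (threshold is ``lambda * log(n)``).
    seg_merge_log2r, seg_merge_mbaf : float
        Post-split merge tolerances on adjacent-segment medians.
    rng_seed : int
        Seed for any stochastic step.
    """

    footprint_fraction: float = 0.01
    delta_f: float = 0.08
    tau_log2r: float = 0.15
    tau_mbaf: float = 0.58
    min_probes: int = 50
    max_total_copy: int = 4
    mono_if_cc_le: int = 0
    informative_baf_window: tuple[float, float] = (0.03, 0.97)
    seg_penalty: float = 10.0
    seg_merge_log2r: float = 0.05
    seg_merge_mbaf: float = 0.02
    fit_weight_log2r: float = 1.0
    fit_weight_mbaf: float = 4.0
    min_informative_probes: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.footprint_fraction < 1.0):
            raise ValueError("footprint_fraction must be in (0, 1)")
        if not (0.0 < self.delta_f < 0.5):
            raise ValueError("delta_f must be in (0, 0.5)")
        if self.max_total_copy < 3:
            raise ValueError("max_total_copy must be >= 3")
        lo, hi = self.informative_baf_window
        if not (0.0 <= lo < 0.5 < hi <= 1.0):
            raise ValueError("informative_baf_window must bracket 0.5 inside [0, 1]")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["informative_baf_window"] = list(self.informative_baf_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "informative_baf_window" in d:
            d["informative_baf_window"] = tuple(d["informative_baf_window"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)
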