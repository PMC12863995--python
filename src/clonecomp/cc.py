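"""Clonal composition (CC) estimation — the pipeline's central computation.

Each copy-number-aberrant segment is assigned the allele-specific copy
state (nT, nB) and overall cellular fraction f that best explain its
median log2R and mirrored BAF under the two-population mixture model.
Fitted fractions are clustered on the f axis; every cluster whose genomic
footprint reaches the clone-calling threshold counts one clone. CC is the
number of passing clusters; CC = 0 is Mono-CC (no detectable
subclonality), CC >= 1 Poly-CC.

Because fractions are clustered directly, tumor purity is never estimated
separately: the dominant aberrant clone simply contributes a cluster like
any other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .config import RunConfig
from .datatypes import ProbeSet, Segment, SegmentSet
from .simulate import expected_baf, expected_log2r

_MIN_AVG_COPY = 0.05  # clamp for the (nT=0, f->1) corner of the grid
F_GRID = np.round(np.arange(0.01, 1.0 + 1e-9, 0.01), 2)  # 1% granularity


@dataclass(frozen=True)
class CopyState:
    """Allele-specific copy state: total and minor-allele copy numbers."""

    n_total: int
    n_minor: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_minor <= self.n_total // 2:
            raise ValueError("need 0 <= n_minor <= floor(n_total/2)")


def aberrant_states(max_total_copy: int = 4) -> list[CopyState]:
    """All states with nT <= cap, excluding the normal (2, 1), ordered by
    the fit tie-break priority (smaller |nT-2|, then larger nB)."""
    states = [
        CopyState(nT, nB)
        for nT in range(max_total_copy + 1)
        for nB in range(nT // 2 + 1)
        if (nT, nB) != (2, 1)
    ]
    states.sort(key=lambda s: (abs(s.n_total - 2), -s.n_minor))
    return states


@dataclass
class SegmentFit:
    """A segment with its fitted copy state and cellular fraction."""

    segment: Segment
    state: CopyState
    f: float
    residual: float
    aberrant: bool = True


@dataclass
class CloneCluster:
    """A group of segment fits sharing one cellular fraction."""

    members: list[SegmentFit]
    centroid_f: float
    footprint_bp: int
    footprint_fraction: float = 0.0
    passes_footprint: bool = False


@dataclass
class CCResult:
    """CC number, Mono/Poly call and the full cluster table for one sample."""

    cc: int
    classification: str  # "Mono" | "Poly"
    clusters: list[CloneCluster]  # all clusters, descending centroid_f
    genome_bp: int
    config: RunConfig
    sample_id: str = "sample"


def is_aberrant(seg: Segment, cfg: RunConfig | None = None) -> bool:
    """Copy-number/allelic aberrance gate on a segment's median signals."""
    cfg = cfg or RunConfig()
    if abs(seg.med_log2r) >= cfg.tau_log2r:
        return True
    return seg.med_mbaf is not None and seg.med_mbaf >= cfg.tau_mbaf


def fraction_from_log2r(l2r: float, n_total: int) -> tuple[float, bool]:
    """Invert the copy mixture: ``f = (2*2^l2r - 2) / (nT - 2)``.

    Returns (f clipped to [0.01, 1], in_range flag). Undefined at nT=2
    (log2R carries no fraction information there — use the BAF channel).
    """
    if n_total == 2:
        raise ValueError("fraction is undefined from log2R at nT=2")
    f = (2.0 * 2.0**l2r - 2.0) / (n_total - 2)
    return float(np.clip(f, 0.01, 1.0)), bool(0.01 <= f <= 1.0)


def fraction_from_mbaf(mbaf: float, n_total: int, n_minor: int) -> tuple[float, bool]:
    """Invert the major-allele mixture: with b = mBAF,
    ``f = (2b - 1) / ((nT - nB - 1) - b*(nT - 2))``.

    Valid while the denominator is positive; raises when the requested
    state cannot produce the observed mBAF direction.
    """
    if not 0.5 <= mbaf <= 1.0:
        raise ValueError("mBAF must lie in [0.5, 1]")
    if (n_total, n_minor) == (2, 1):
        raise ValueError("the balanced diploid state has no fraction signal")
    denom = (n_total - n_minor - 1) - mbaf * (n_total - 2)
    if denom <= 0:
        raise ValueError(f"state ({n_total},{n_minor}) incompatible with mBAF={mbaf}")
    f = (2.0 * mbaf - 1.0) / denom
    return float(np.clip(f, 0.01, 1.0)), bool(0.01 <= f <= 1.0)


def _model_grid(states: list[CopyState]):
    """Expected (log2R, mBAF) over the full (state, f) grid.

    Returns arrays of shape (n_states, n_f). The average copy is clamped
    away from zero so the homozygous-deletion corner stays finite.
    """
    nT = np.array([s.n_total for s in states], dtype=float)[:, None]
    nB = np.array([s.n_minor for s in states], dtype=float)[:, None]
    f = F_GRID[None, :]
    avg = np.maximum(2.0 * (1.0 - f) + f * nT, _MIN_AVG_COPY)
    exp_l2r = np.log2(avg / 2.0)
    baf = ((1.0 - f) + f * nB) / avg
    exp_mbaf = 0.5 + np.abs(baf - 0.5)
    return exp_l2r, exp_mbaf


def fit_segment(seg: Segment, cfg: RunConfig | None = None) -> SegmentFit:
    """Grid-search the best (copy state, fraction) for an aberrant segment.

    Minimizes ``w_l*(med_log2r - E[log2R])^2 + w_b*(med_mbaf - E[mBAF])^2``
    over all states with nT <= max_total_copy and f in {0.01..1.00}. The
    BAF term is weighted 4:1 (medians of many heterozygous probes make it
    the quieter channel); it is dropped when the segment has no mBAF. Ties
    go to smaller |nT-2|, then larger nB, then smaller f.
    """
    cfg = cfg or RunConfig()
    states = aberrant_states(cfg.max_total_copy)
    exp_l2r, exp_mbaf = _model_grid(states)
    resid = cfg.fit_weight_log2r * (seg.med_log2r - exp_l2r) ** 2
    if seg.med_mbaf is not None:
        resid = resid + cfg.fit_weight_mbaf * (seg.med_mbaf - exp_mbaf) ** 2
    # states are ordered by tie-break priority and F_GRID ascending, so the
    # first argmin hit is the tie-break winner
    idx = int(np.argmin(np.round(resid, 12)))
    i, j = divmod(idx, resid.shape[1])
    return SegmentFit(
        segment=seg, state=states[i], f=float(F_GRID[j]), residual=float(resid[i, j])
    )


def cluster_fractions(fits: list[SegmentFit], cfg: RunConfig | None = None) -> list[CloneCluster]:
    """1-D agglomerative clustering of fitted fractions.

    Fits are sorted by f (ties broken by genomic order); a new cluster
    starts whenever the next fraction is more than ``delta_f`` from the
    running length-weighted centroid. Clusters are returned by descending
    centroid.
    """
    cfg = cfg or RunConfig()
    if not fits:
        return []
    from .datatypes import AUTOSOMES

    chrom_rank = {c: i for i, c in enumerate(AUTOSOMES)}
    ordered = sorted(
        fits, key=lambda t: (t.f, chrom_rank[t.segment.chrom], t.segment.start_bp)
    )
    clusters: list[CloneCluster] = []
    members: list[SegmentFit] = []
    centroid = wsum = 0.0

    def flush():
        if members:
            bp = sum(m.segment.length_bp for m in members)
            clusters.append(CloneCluster(list(members), centroid_f=centroid, footprint_bp=bp))

    for fit in ordered:
        w = fit.segment.length_bp
        if members and abs(fit.f - centroid) > cfg.delta_f:
            flush()
            members, centroid, wsum = [], 0.0, 0.0
        members.append(fit)
        centroid = (centroid * wsum + fit.f * w) / (wsum + w)
        wsum += w
    flush()
    clusters.sort(key=lambda c: -c.centroid_f)
    return clusters


def compute_cc(segset: SegmentSet, cfg: RunConfig | None = None,
               sample_id: str | None = None) -> CCResult:
    """CC number and Mono/Poly class from a segmented sample.

    The footprint denominator is the analyzed autosomal span
    (``segset.genome_bp``), not the full genome.
    """
    cfg = cfg or RunConfig()
    if segset.genome_bp <= 0:
        raise ValueError("genome_bp must be positive")
    fits = [fit_segment(s, cfg) for s in segset.segments if is_aberrant(s, cfg)]
    clusters = cluster_fractions(fits, cfg)
    for cl in clusters:
        cl.footprint_fraction = cl.footprint_bp / segset.genome_bp
        cl.passes_footprint = cl.footprint_fraction >= cfg.footprint_fraction
    cc = sum(cl.passes_footprint for cl in clusters)
    classification = "Mono" if cc <= cfg.mono_if_cc_le else "Poly"
    return CCResult(
        cc=cc,
        classification=classification,
        clusters=clusters,
        genome_bp=segset.genome_bp,
        config=cfg,
        sample_id=sample_id or segset.sample_id,
    )


class ClonalCompositionEstimator(BaseEstimator):
    """End-to-end CC estimation, scikit-learn style.

    ``fit`` accepts a :class:`ProbeSet` (segmented internally) or a
    pre-computed :class:`SegmentSet` and populates ``cc_``,
    ``classification_``, ``clusters_`` and ``result_``.

    Parameters mirror :class:`~clonecomp.config.RunConfig`; see there for
    units and defaults.
    """

    def __init__(
        self,
        footprint_fraction: float = 0.01,
        delta_f: float = 0.08,
        tau_log2r: float = 0.15,
        tau_mbaf: float = 0.58,
        min_probes: int = 50,
        max_total_copy: int = 4,
        mono_if_cc_le: int = 0,
        informative_baf_window: tuple[float, float] = (0.03, 0.97),
        seg_penalty: float = 10.0,
    ):
        self.footprint_fraction = footprint_fraction
        self.delta_f = delta_f
        self.tau_log2r = tau_log2r
        self.tau_mbaf = tau_mbaf
        self.min_probes = min_probes
        self.max_total_copy = max_total_copy
        self.mono_if_cc_le = mono_if_cc_le
        self.informative_baf_window = informative_baf_window
        self.seg_penalty = seg_penalty

    def _config(self) -> RunConfig:
        return RunConfig(
            footprint_fraction=self.footprint_fraction,
            delta_f=self.delta_f,
            tau_log2r=self.tau_log2r,
            tau_mbaf=self.tau_mbaf,
            min_probes=self.min_probes,
            max_total_copy=self.max_total_copy,
            mono_if_cc_le=self.mono_if_cc_le,
            informative_baf_window=tuple(self.informative_baf_window),
            seg_penalty=self.seg_penalty,
        )

    def fit(self, X, y=None) -> "ClonalCompositionEstimator":
        cfg = self._config()
        if isinstance(X, SegmentSet):
            segset = X
        else:
            from .segment import segment_genome

            probes = X if isinstance(X, ProbeSet) else ProbeSet(X)
            segset = segment_genome(probes, cfg)
        result = compute_cc(segset, cfg)
        self.segments_ = segset
        self.result_ = result
        self.cc_ = result.cc
        self.classification_ = result.classification
        self.clusters_ = result.clusters
        return self

    def predict(self, X) -> int:
        """CC number of a single sample (fits and returns ``cc_``)."""
        return self.fit(X).cc_
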