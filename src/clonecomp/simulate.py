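"""Synthetic clonal architectures rendered into noisy SNP-array data.

The generative model is a two-population mixture at every locus: a fraction
``f`` of cells (tumor purity times cancer-cell fraction of the clone
carrying the event) has total/minor copy numbers ``(nT, nB)``, the rest are
diploid heterozygous ``(2, 1)``. The array reports

* ``log2R = log2((2(1-f) + f*nT) / 2)`` — total copy signal, and
* ``BAF = ((1-f) + f*nB) / (2(1-f) + f*nT)`` at germline-heterozygous loci.

Noise emulates FFPE-grade arrays: per-probe Gaussian log2R noise and
Beta-distributed BAF around the expected value; germline-homozygous loci
cluster near 0/1 and must be excluded downstream. Everything is
deterministic given the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import AUTOSOMES, CohortTable, ProbeSet

# GRCh38 autosome lengths (bp)
CHROM_LENGTHS_BP: dict[str, int] = {
    "1": 248956422, "2": 242193529, "3": 198295559, "4": 190214555,
    "5": 181538259, "6": 170805979, "7": 159345973, "8": 145138636,
    "9": 138394717, "10": 133797422, "11": 135086622, "12": 133275309,
    "13": 114364328, "14": 107043718, "15": 101991189, "16": 90338345,
    "17": 83257441, "18": 80373285, "19": 58617616, "20": 64444167,
    "21": 46709983, "22": 50818468,
}
GENOME_BP: int = sum(CHROM_LENGTHS_BP.values())


def expected_log2r(f: float, n_total: int) -> float:
    """Expected log2 ratio of a two-population copy mixture.

    ``log2((2(1-f) + f*nT) / 2)``; zero when the average copy is 2.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"cellular fraction f={f} outside [0, 1]")
    if n_total < 0:
        raise ValueError("n_total must be >= 0")
    avg = 2.0 * (1.0 - f) + f * n_total
    if avg <= 0.0:
        raise ValueError("homozygous deletion in all cells: log2R undefined")
    return math.log2(avg / 2.0)


def expected_baf(f: float, n_total: int, n_minor: int) -> float:
    """Expected B-allele frequency at a germline-heterozygous locus.

    ``((1-f) + f*nB) / (2(1-f) + f*nT)``; 0.5 when f=0 or the state is the
    balanced diploid (2, 1).
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"cellular fraction f={f} outside [0, 1]")
    if not 0 <= n_minor <= n_total:
        raise ValueError(f"need 0 <= nB <= nT, got nB={n_minor}, nT={n_total}")
    denom = 2.0 * (1.0 - f) + f * n_total
    if denom <= 0.0:
        raise ValueError("homozygous deletion in all cells: BAF undefined")
    return ((1.0 - f) + f * n_minor) / denom


@dataclass
class CNVEvent:
    """One copy-number event carried by one clone (1-based inclusive)."""

    chrom: str
    start_bp: int
    end_bp: int
    n_total: int
    n_minor: int
    clone_id: str

    def __post_init__(self) -> None:
        if self.chrom not in AUTOSOMES:
            raise ValueError(f"event on non-autosome {self.chrom!r}")
        if self.end_bp < self.start_bp:
            raise ValueError("event end < start")
        if not 0 <= self.n_minor <= self.n_total // 2:
            raise ValueError("need 0 <= n_minor <= floor(n_total/2)")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class ClonalArchitecture:
    """Ground truth: purity, clone fractions and their CNV events.

    ``clones`` maps clone_id -> cancer-cell fraction c_k in (0, 1]; the
    overall cellular fraction of an event is ``f = purity * c_k``. Events
    of different clones are disjoint unless ``allow_nested`` (nested
    events are resolved last-writer-wins; their fraction algebra is a
    simplification).
    """

    purity: float
    clones: dict[str, float]
    events: list[CNVEvent] = field(default_factory=list)
    allow_nested: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.purity <= 1.0:
            raise ValueError("purity must be in (0, 1]")
        for cid, ccf in self.clones.items():
            if not 0.0 < ccf <= 1.0:
                raise ValueError(f"clone {cid}: cancer-cell fraction must be in (0, 1]")
        for ev in self.events:
            if ev.clone_id not in self.clones:
                raise ValueError(f"event references unknown clone {ev.clone_id!r}")
        if not self.allow_nested:
            by_chrom: dict[str, list[CNVEvent]] = {}
            for ev in self.events:
                by_chrom.setdefault(ev.chrom, []).append(ev)
            for chrom, evs in by_chrom.items():
                evs = sorted(evs, key=lambda e: e.start_bp)
                for a, b in zip(evs, evs[1:]):
                    if b.start_bp <= a.end_bp:
                        raise ValueError(
                            f"overlapping events on chr{chrom}: "
                            f"({a.start_bp}-{a.end_bp}) vs ({b.start_bp}-{b.end_bp}); "
                            "set allow_nested=True to permit"
                        )

    def event_fraction(self, ev: CNVEvent) -> float:
        return self.purity * self.clones[ev.clone_id]

    @classmethod
    def from_json(cls, path: str | Path) -> "ClonalArchitecture":
        with open(path) as fh:
            d = json.load(fh)
        events = [CNVEvent(**e) for e in d.get("events", [])]
        return cls(
            purity=d["purity"],
            clones=dict(d["clones"]),
            events=events,
            allow_nested=d.get("allow_nested", False),
        )

    def to_json(self, path: str | Path) -> None:
        d = {
            "purity": self.purity,
            "clones": self.clones,
            "allow_nested": self.allow_nested,
            "events": [vars(e) for e in self.events],
        }
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)
            fh.write("\n")


@dataclass
class NoiseModel:
    """FFPE-grade array noise. ``sigma_log2r=0`` / ``baf_concentration=inf``
    render expected values exactly (the zero-noise shortcut)."""

    sigma_log2r: float = 0.25
    baf_concentration: float = 60.0
    het_fraction: float = 0.35
    n_probes: int = 220_000
    # Homozygous clusters are far tighter than heterozygous ones on real
    # arrays; a loose value here leaks hom probes through the informative
    # BAF window and biases segment mBAF upward.
    hom_concentration: float = 2000.0

    def __post_init__(self) -> None:
        if self.sigma_log2r < 0:
            raise ValueError("sigma_log2r must be >= 0")
        if not (self.baf_concentration > 2):
            raise ValueError("baf_concentration must be > 2 (may be inf)")
        if not (self.hom_concentration > 2):
            raise ValueError("hom_concentration must be > 2 (may be inf)")
        if not 0.0 < self.het_fraction < 1.0:
            raise ValueError("het_fraction must be in (0, 1)")

    @classmethod
    def zero_noise(cls, n_probes: int = 220_000, het_fraction: float = 0.35) -> "NoiseModel":
        return cls(
            sigma_log2r=0.0,
            baf_concentration=math.inf,
            het_fraction=het_fraction,
            n_probes=n_probes,
            hom_concentration=math.inf,
        )


@dataclass
class TruthRecord:
    """Simulator ground truth for one sample."""

    architecture: ClonalArchitecture
    footprint_fraction: float
    expected_cc: int


def truth_cc(arch: ClonalArchitecture, footprint_fraction: float = 0.01,
             genome_bp: int = GENOME_BP) -> int:
    """Expected CC: distinct cellular fractions (rounded to 0.01) among
    aberrant events whose aggregate span reaches the footprint."""
    span_by_f: dict[float, int] = {}
    for ev in arch.events:
        if (ev.n_total, ev.n_minor) == (2, 1):
            continue
        f = round(arch.event_fraction(ev), 2)
        span_by_f[f] = span_by_f.get(f, 0) + ev.length_bp
    return sum(1 for span in span_by_f.values() if span >= footprint_fraction * genome_bp)


_HOM_MU = (0.02, 0.98)


def simulate_sample(
    arch: ClonalArchitecture,
    noise: NoiseModel | None = None,
    seed: int = 0,
    footprint_fraction: float = 0.01,
    sample_id: str = "sim",
) -> tuple[ProbeSet, TruthRecord]:
    """Render an architecture into a probe-level :class:`ProbeSet`.

    Probes are spread over the 22 autosomes proportionally to length;
    heterozygous loci draw BAF ~ Beta(mu*kappa, (1-mu)*kappa) around the
    expected allele fraction, homozygous loci near 0.02/0.98, and log2R is
    Gaussian around the expected mixture value. Byte-identical given seed.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)

    chroms_all, pos_all = [], []
    remaining, rem_len = noise.n_probes, GENOME_BP
    for chrom in AUTOSOMES:
        length = CHROM_LENGTHS_BP[chrom]
        n_c = int(round(remaining * length / rem_len))
        remaining -= n_c
        rem_len -= length
        # unique uniform positions; np.unique also sorts (collisions are
        # ~1e-3 expected per chromosome at 220k probes, silently dropped)
        pos = np.unique(rng.integers(1, length + 1, size=n_c))
        chroms_all.append(np.full(len(pos), chrom, dtype=object))
        pos_all.append(pos)
    chrom_arr = np.concatenate(chroms_all)
    pos_arr = np.concatenate(pos_all)
    n = len(pos_arr)

    n_total = np.full(n, 2, dtype=np.int64)
    n_minor = np.full(n, 1, dtype=np.int64)
    frac = np.zeros(n, dtype=float)
    for ev in arch.events:
        mask = (chrom_arr == ev.chrom) & (pos_arr >= ev.start_bp) & (pos_arr <= ev.end_bp)
        n_total[mask] = ev.n_total
        n_minor[mask] = ev.n_minor
        frac[mask] = arch.event_fraction(ev)

    avg_copy = 2.0 * (1.0 - frac) + frac * n_total
    if np.any(avg_copy <= 0):
        raise ValueError("architecture deletes all copies in all cells somewhere")
    exp_l2r = np.log2(avg_copy / 2.0)
    mu_het = ((1.0 - frac) + frac * n_minor) / avg_copy

    het = rng.random(n) < noise.het_fraction
    # which parental allele is labeled "B" is arbitrary -> random phase;
    # mirroring downstream folds both bands back together
    flip = rng.random(n) < 0.5
    hom_hi = rng.random(n) < 0.5
    mu = np.where(het, np.where(flip, 1.0 - mu_het, mu_het),
                  np.where(hom_hi, _HOM_MU[1], _HOM_MU[0]))

    kappa = np.where(het, noise.baf_concentration, noise.hom_concentration)
    finite = np.isfinite(kappa)
    if not finite.any():
        baf = mu
    else:
        mu_c = np.clip(mu, 0.0025, 0.9975)
        k_safe = np.where(finite, kappa, 4.0)
        drawn = rng.beta(mu_c * k_safe, (1.0 - mu_c) * k_safe)
        baf = np.where(finite, drawn, mu)  # kappa -> inf renders mu exactly
    if noise.sigma_log2r > 0:
        l2r = exp_l2r + rng.normal(0.0, noise.sigma_log2r, size=n)
    else:
        l2r = exp_l2r

    probes = ProbeSet(
        pd.DataFrame(
            {"chrom": chrom_arr, "pos": pos_arr, "log2r": l2r, "baf": np.clip(baf, 0.0, 1.0)}
        ),
        sample_id=sample_id,
    )
    truth = TruthRecord(
        architecture=arch,
        footprint_fraction=footprint_fraction,
        expected_cc=truth_cc(arch, footprint_fraction),
    )
    return probes, truth


# Copy states cycled over the events of successive clones; (4, 2) is avoided
# because it is signal-degenerate with (3, 1) at twice the fraction.
_EVENT_STATES: tuple[tuple[int, int], ...] = ((1, 0), (3, 1), (2, 0), (3, 0))


def architecture_from_fractions(
    fractions: list[float] | tuple[float, ...],
    span_fraction: float = 0.025,
    states: tuple[tuple[int, int], ...] = _EVENT_STATES,
) -> ClonalArchitecture:
    """Build a k-clone architecture with one event per clone.

    Each clone's overall cellular fraction equals the requested value
    (purity is set to the largest fraction, the top clone is clonal);
    events sit on distinct chromosomes and each spans ``span_fraction``
    of the genome.
    """
    fractions = sorted(fractions, reverse=True)
    if not fractions:
        return ClonalArchitecture(purity=0.7, clones={"c1": 1.0}, events=[])
    purity = fractions[0]
    clones = {f"c{i + 1}": f / purity for i, f in enumerate(fractions)}
    events = []
    for i, f in enumerate(fractions):
        chrom = AUTOSOMES[i % 12]  # large chromosomes only
        span = int(span_fraction * GENOME_BP)
        if span > CHROM_LENGTHS_BP[chrom] - 2_000_000:
            raise ValueError("event span too large for one chromosome")
        start = 1_000_001
        nT, nB = _detectable_state(f, states[i % len(states)])
        events.append(
            CNVEvent(chrom=chrom, start_bp=start, end_bp=start + span - 1,
                     n_total=nT, n_minor=nB, clone_id=f"c{i + 1}")
        )
    return ClonalArchitecture(purity=purity, clones=clones, events=events)


def _detectable_state(f: float, preferred: tuple[int, int],
                      tau_log2r: float = 0.15, tau_mbaf: float = 0.58) -> tuple[int, int]:
    """Pick an event state whose zero-noise signals clear the aberrance gates
    at fraction ``f`` (a weak event at low fraction is intrinsically
    invisible to the pipeline and would not represent a callable clone)."""
    for nT, nB in (preferred, (2, 0), (1, 0), (4, 0)):
        l2r = expected_log2r(f, nT)
        mbaf = 0.5 + abs(expected_baf(f, nT, nB) - 0.5)
        if abs(l2r) >= tau_log2r or mbaf >= tau_mbaf:
            return nT, nB
    return preferred


# --- cohort simulation -----------------------------------------------------

# Study-scale defaults: Mono 5-yr EFS ~69%, Poly ~39% (hazard ratio ~2.68),
# OS hazard ratio ~1.27, CC histogram as observed in a 74-patient cohort.
DEFAULT_CC_DIST_MONO = {0: 1.0}
DEFAULT_CC_DIST_POLY = {1: 46 / 59, 2: 11 / 59, 3: 1 / 59, 4: 1 / 59}
DEFAULT_BASELINE_HAZARD = -math.log(0.691) / (5 * 365.25)  # per day, EFS Mono
DEFAULT_OS_BASELINE_HAZARD = -math.log(0.662) / (5 * 365.25)


def simulate_cohort(
    n_patients: int,
    poly_fraction: float = 59 / 74,
    hazard_ratio: float = 2.68,
    os_hazard_ratio: float = 1.27,
    baseline_hazard: float = DEFAULT_BASELINE_HAZARD,
    censoring_max_days: float | None = 2989.0,
    seed: int = 0,
    cc_dist_mono: dict[int, float] = DEFAULT_CC_DIST_MONO,
    cc_dist_poly: dict[int, float] = DEFAULT_CC_DIST_POLY,
    outdir: str | Path | None = None,
    render_probes: bool = False,
    noise: NoiseModel | None = None,
) -> CohortTable:
    """Simulate a cohort of Mono/Poly-CC patients with survival outcomes.

    Event times are exponential with group-specific hazard (Poly hazard =
    baseline * hazard_ratio); censoring is independent uniform on
    (0, censoring_max_days], or absent when ``censoring_max_days`` is None.
    COO labels are drawn at the study's GCB/ABC/Unclassified proportions,
    independent of CC class. With ``outdir`` the clinical CSV (and
    optionally per-patient probe TSVs plus a truth JSON) are written.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if hazard_ratio <= 0 or os_hazard_ratio <= 0:
        raise ValueError("hazard ratios must be positive")
    if censoring_max_days is not None and censoring_max_days <= 0:
        raise ValueError("degenerate censoring window: censoring_max_days must be > 0")
    rng = np.random.default_rng(seed)

    is_poly = rng.random(n_patients) < poly_fraction
    if is_poly.all() or (~is_poly).all():  # both groups must exist
        is_poly[0] = not is_poly[0]

    def draw_cc(poly: bool) -> int:
        dist = cc_dist_poly if poly else cc_dist_mono
        vals, probs = zip(*sorted(dist.items()))
        return int(rng.choice(vals, p=np.asarray(probs) / sum(probs)))

    cc = np.array([draw_cc(p) for p in is_poly])
    hz_efs = np.where(is_poly, baseline_hazard * hazard_ratio, baseline_hazard)
    hz_os = np.where(is_poly, DEFAULT_OS_BASELINE_HAZARD * os_hazard_ratio,
                     DEFAULT_OS_BASELINE_HAZARD)
    t_efs = rng.exponential(1.0 / hz_efs)
    t_os = rng.exponential(1.0 / hz_os)
    if censoring_max_days is None:
        efs_days, efs_event = t_efs, np.ones(n_patients, dtype=int)
        os_days, os_event = t_os, np.ones(n_patients, dtype=int)
    else:
        cens = rng.uniform(0.0, censoring_max_days, size=n_patients)
        efs_days = np.minimum(t_efs, cens)
        efs_event = (t_efs <= cens).astype(int)
        os_days = np.minimum(t_os, cens)
        os_event = (t_os <= cens).astype(int)

    coo = rng.choice(["GCB", "ABC", "Unclassified"], size=n_patients,
                     p=[30 / 73, 35 / 73, 8 / 73])
    df = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:04d}" for i in range(n_patients)],
            "cc": cc,
            "cc_class": np.where(is_poly, "Poly", "Mono"),
            "coo": coo,
            "efs_days": np.round(efs_days, 3),
            "efs_event": efs_event,
            "os_days": np.round(os_days, 3),
            "os_event": os_event,
        }
    )
    cohort = CohortTable(df)

    if outdir is not None:
        from .io import write_clinical_csv, write_probe_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_clinical_csv(cohort, outdir / "cohort.csv")
        if render_probes:
            truth: dict[str, int] = {}
            for i, row in df.iterrows():
                fractions = [0.7 - 0.18 * j for j in range(int(row["cc"]))]
                arch = architecture_from_fractions(fractions)
                probes, rec = simulate_sample(
                    arch, noise=noise, seed=int(rng.integers(2**31)),
                    sample_id=row["patient_id"],
                )
                write_probe_table(probes, outdir / f"{row['patient_id']}.tsv")
                truth[row["patient_id"]] = rec.expected_cc
            with open(outdir / "truth.json", "w") as fh:
                json.dump(truth, fh, indent=2)
    return cohort
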