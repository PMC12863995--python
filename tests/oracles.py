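"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: plain-Python
enumeration and textbook formulas only, so agreement with the pipeline is
a genuine cross-check.
"""

import math

import numpy as np
from scipy import stats as sps


def fisher_2x2_oracle(table) -> float:
    """Two-sided Fisher p by full enumeration of the hypergeometric support."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d
    support = range(max(0, c1 - (c + d)), min(r1, c1) + 1)
    pmf = {k: sps.hypergeom.pmf(k, n, r1, c1) for k in support}
    return sum(p for p in pmf.values() if p <= pmf[a] * (1 + 1e-7))


def segment_fit_oracle(seg, cfg):
    """Brute-force (state, fraction) grid minimizer with explicit tie-break
    (smaller |nT-2|, then larger nB, then smaller f)."""
    best = None
    for nT in range(cfg.max_total_copy + 1):
        for nB in range(nT // 2 + 1):
            if (nT, nB) == (2, 1):
                continue
            for fi in range(1, 101):
                f = fi / 100.0
                avg = max(2 * (1 - f) + f * nT, 0.05)
                el = math.log2(avg / 2)
                r = cfg.fit_weight_log2r * (seg.med_log2r - el) ** 2
                if seg.med_mbaf is not None:
                    mu = ((1 - f) + f * nB) / avg
                    eb = 0.5 + abs(mu - 0.5)
                    r += cfg.fit_weight_mbaf * (seg.med_mbaf - eb) ** 2
                key = (round(r, 12), abs(nT - 2), -nB, f)
                if best is None or key < best[0]:
                    best = (key, (nT, nB, f))
    return best[1]
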