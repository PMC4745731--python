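"""Independent reference implementations used as test oracles.

These deliberately mirror the scoring definitions with naive nested loops and
direct formulas, sharing no code with the package's vectorised paths.
"""

from __future__ import annotations

import math
from itertools import count

import numpy as np


def naive_pas(stats, db, mode="standard"):
    """Three-nested-loop PAS: pathways x members x samples."""
    n_s = len(stats.sample_ids)
    pos = {g: i for i, g in enumerate(stats.genes)}
    out = np.zeros((len(db), n_s))
    for pi, pw in enumerate(db):
        measured = [g for g in pw.members if g in pos]
        if not measured:
            out[pi, :] = np.nan
            continue
        for si in range(n_s):
            total = 0.0
            for gene in measured:
                gi = pos[gene]
                arr = 1 if mode == "killermab" else pw.members[gene]
                btif = int(stats.btif[gi, si])
                if btif:
                    total += arr * btif * math.log10(stats.cnr[gi, si])
            out[pi, si] = total
    return out


def naive_ds(pas_values, pathway_ids, db, dtm):
    """Quadruple loop over (drug, target, pathway, sample)."""
    n_s = pas_values.shape[1]
    row = {p: i for i, p in enumerate(pathway_ids)}
    out = np.zeros((len(dtm.drugs), n_s))
    for di, drug in enumerate(dtm.drugs):
        for target in dtm[drug]:
            for pw in db:
                if target not in pw.members or pw.pathway_id not in row:
                    continue
                v = pas_values[row[pw.pathway_id]]
                for si in range(n_s):
                    if not np.isnan(v[si]):
                        out[di, si] += pw.amcf * v[si]
    return out


def prediction_interval_p(case_value, control_values):
    """Two-sided p of one new log2 observation vs a control sample."""
    from scipy import stats as sps

    lc = np.log2(np.asarray(control_values, dtype=float))
    x = math.log2(case_value)
    m = len(lc)
    s = lc.std(ddof=1)
    if s == 0:
        return 1.0 if x == lc.mean() else 0.0
    t = (x - lc.mean()) / (s * math.sqrt(1 + 1 / m))
    return float(2 * sps.t.sf(abs(t), df=m - 1))


def pearson_direct(x, y):
    """Pearson r by the covariance / (sigma_x sigma_y) formula."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    dy = y - y.mean()
    return float((dx * dy).sum() / math.sqrt((dx * dx).sum() * (dy * dy).sum()))


def _hypergeom_prob(a, r1, r2, c1):
    """P(top-left cell = a) for fixed margins r1, r2 (rows) and c1 (col 1)."""
    return (
        math.comb(r1, a) * math.comb(r2, c1 - a) / math.comb(r1 + r2, c1)
    )


def fisher_two_sided_enumerated(table):
    """Two-sided Fisher exact p by full enumeration of tables at fixed margins."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    p_obs = _hypergeom_prob(a, r1, r2, c1)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = _hypergeom_prob(k, r1, r2, c1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)
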