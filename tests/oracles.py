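"""Independent brute-force re-implementations used as oracles in tests.

Everything here is written with plain loops and dictionaries, sharing no code
path with the package (the Lowess smoother itself is the one shared
primitive, called with identical parameters).
"""

from __future__ import annotations

import math

import numpy as np
import statsmodels.api as sm
from scipy import stats


def oracle_normalize(probes, span=0.3, iterations=3):
    """Step-by-step probe-table normalization on a small complete table.

    Returns {gene: {sample: value}} of quantile-normalized log2 gene values.
    Assumes every gene is measured in every sample (no missingness) and all
    intensities are linear-scale.
    """
    # 1. median over placements per (sample, probe)
    placements = {}
    meta = {}
    for row in probes.itertuples(index=False):
        key = (row.sample_id, row.probe_id)
        placements.setdefault(key, []).append(float(row.intensity))
        meta[key] = (row.gene_id, int(row.dx))
    medians = {}
    for key, vals in placements.items():
        vals = sorted(vals)
        n = len(vals)
        if n % 2 == 1:
            med = vals[n // 2]
        else:
            med = 0.5 * (vals[n // 2 - 1] + vals[n // 2])
        medians[key] = math.log2(med)

    samples = sorted({s for s, _ in medians})
    genes = sorted({g for g, _ in meta.values()})

    # 2-4. per sample: dx/dy pairs, lowess trend anchored at 0, correction
    corrected = {}
    for sample in samples:
        ref = {}
        for (s, probe), (gene, dx) in meta.items():
            if s == sample and dx == 0:
                ref[gene] = medians[(s, probe)]
        dxs, dys = [], []
        for (s, probe), (gene, dx) in meta.items():
            if s == sample and gene in ref:
                dxs.append(float(dx))
                dys.append(medians[(s, probe)] - ref[gene])
        adx = np.array(dxs, dtype=float)
        ady = np.array(dys, dtype=float)
        fit0 = sm.nonparametric.lowess(ady, adx, frac=span, it=0,
                                       return_sorted=False)
        scale = np.median(np.abs(ady - fit0))
        if iterations > 0 and scale > 1e-12 * max(1.0, float(np.max(np.abs(ady)))):
            with np.errstate(invalid="ignore", divide="ignore"):
                values = sm.nonparametric.lowess(
                    ady, adx, frac=span, it=iterations, return_sorted=False
                )
            if not np.isfinite(values).all():
                values = fit0
        else:
            values = fit0
        grid = {}
        for x, v in zip(adx, values):
            grid.setdefault(float(x), float(v))
        grid_x = sorted(grid)
        grid_y = [grid[x] for x in grid_x]
        anchor = float(np.interp(0.0, grid_x, grid_y))
        for (s, probe), (gene, dx) in meta.items():
            if s == sample:
                off = float(np.interp(float(dx), grid_x, grid_y)) - anchor
                corrected[(s, probe)] = medians[(s, probe)] - off

    # 5. per-gene median of corrected probes
    matrix = {g: {} for g in genes}
    for sample in samples:
        for gene in genes:
            vals = sorted(
                corrected[(s, probe)]
                for (s, probe), (g, _) in meta.items()
                if s == sample and g == gene
            )
            n = len(vals)
            med = (
                vals[n // 2]
                if n % 2 == 1
                else 0.5 * (vals[n // 2 - 1] + vals[n // 2])
            )
            matrix[gene][sample] = med

    # 6. quantile normalization (equal-length complete columns, no ties)
    sorted_cols = {s: sorted(matrix[g][s] for g in genes) for s in samples}
    ref_dist = [
        sum(sorted_cols[s][i] for s in samples) / len(samples)
        for i in range(len(genes))
    ]
    out = {g: {} for g in genes}
    for s in samples:
        order = sorted(genes, key=lambda g: matrix[g][s])
        for rank, gene in enumerate(order):
            out[gene][s] = ref_dist[rank]
    return out


def oracle_detect_window(y, t, w_min, r2_min):
    """Exhaustive linear-window search mirroring the published selection rule."""
    n = len(y)
    candidates = []
    for start in range(n):
        for end in range(start + w_min - 1, n):
            seg = slice(start, end + 1)
            res = stats.linregress(t[seg], y[seg])
            if np.var(y[seg]) == 0:
                r2 = 0.0
            else:
                r2 = res.rvalue**2
            if res.slope > 0 and r2 >= r2_min:
                candidates.append((end - start + 1, r2, -start, (start, end)))
    if candidates:
        length, r2, negstart, window = max(candidates)
        return window[0], window[1], False
    best = None
    for start in range(n - w_min + 1):
        seg = slice(start, start + w_min)
        res = stats.linregress(t[seg], y[seg])
        r2 = 0.0 if np.var(y[seg]) == 0 else res.rvalue**2
        if best is None or r2 > best[0]:
            best = (r2, start)
    return best[1], best[1] + w_min - 1, True


def oracle_ppp_class(r, d, c_thresh, d_thresh):
    corr = "none"
    if r > c_thresh:
        corr = "positive"
    if r < -c_thresh:
        corr = "negative"
    ind = "0"
    if d > d_thresh:
        ind = "+"
    if d < -d_thresh:
        ind = "-"
    return corr, ind
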