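"""Probe-to-gene normalization for custom multi-probe two-color arrays.

The pipeline collapses replicate placements, removes the 3'-positional
intensity bias (reverse-transcription attenuation increasing with a probe's
distance ``dx`` from the gene's 3'-most probe, ``P_last``), summarizes probes
into gene values and equalizes sample distributions:

1. median over the 3-4 placements of each probe (linear scale);
2. per sample, pair every probe's ``dx`` with
   ``dy = log2(intensity) - log2(intensity of P_last)``;
3. Lowess fit of the dy-vs-dx trend, anchored to 0 at ``dx = 0``;
4. subtract the fitted trend from every probe's log2 intensity;
5. per gene, median over its corrected probes;
6. percentile (quantile) normalization across samples.

All log transforms use base 2, the microarray convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata

from .exceptions import DataError, FitError

logger = logging.getLogger(__name__)

_KEY_COLS = ["sample_id", "strain_id", "condition", "gene_id", "probe_id", "dx"]


@dataclass(frozen=True)
class BiasCurve:
    """Piecewise-linear 3'-positional bias: log2 offset as a function of dx.

    Linear interpolation between grid points, constant beyond the fitted
    range; the offset at dx=0 is 0 by construction (P_last is its own
    reference).
    """

    support: np.ndarray
    offset: np.ndarray

    def __post_init__(self):
        if len(self.support) != len(self.offset) or len(self.support) == 0:
            raise DataError("bias curve needs matching non-empty grids")

    def __call__(self, dx) -> np.ndarray:
        return np.interp(np.asarray(dx, dtype=float), self.support, self.offset)


def _require_columns(table: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise DataError(f"probe table is missing columns {missing}")


def to_log2(probes: pd.DataFrame) -> pd.DataFrame:
    """Return the table with intensities on the log2 scale."""
    out = probes.copy()
    if "scale" in out.columns and (out["scale"] == "linear").any():
        lin = out["scale"] == "linear"
        vals = out.loc[lin, "intensity"]
        if (vals <= 0).any():
            raise DataError("linear-scale intensities must be > 0")
        out.loc[lin, "intensity"] = np.log2(vals)
        out.loc[lin, "scale"] = "log2"
    return out


def median_over_replicates(probes: pd.DataFrame) -> pd.DataFrame:
    """Collapse the 3-4 placements of each probe to their median intensity.

    Even placement counts take the midpoint of the two central values.
    """
    if len(probes) == 0:
        raise DataError("empty probe table")
    _require_columns(probes, ["sample_id", "gene_id", "probe_id", "intensity"])
    keys = [c for c in _KEY_COLS if c in probes.columns]
    if "scale" in probes.columns:
        keys.append("scale")
    out = (
        probes.groupby(keys, sort=False, observed=True)["intensity"]
        .median()
        .reset_index()
    )
    return out


def compute_dx_dy(probes: pd.DataFrame) -> pd.DataFrame:
    """Pair each probe with its gene's P_last probe, per sample.

    Returns one row per sample x probe with columns
    ``sample_id, gene_id, probe_id, dx, dy`` where
    ``dy = log2(intensity) - log2(intensity of the dx=0 probe)``.  P_last
    probes contribute (0, 0).  Genes lacking a dx=0 probe in a sample are
    skipped with a logged warning.
    """
    _require_columns(probes, ["sample_id", "gene_id", "probe_id", "dx", "intensity"])
    table = to_log2(probes)
    ref = table[table["dx"] == 0][["sample_id", "gene_id", "intensity"]].rename(
        columns={"intensity": "_ref"}
    )
    merged = table.merge(ref, on=["sample_id", "gene_id"], how="left")
    dropped = merged["_ref"].isna()
    if dropped.any():
        n_genes = merged.loc[dropped, ["sample_id", "gene_id"]].drop_duplicates()
        logger.warning(
            "skipping %d sample/gene pairs without a dx=0 (P_last) probe",
            len(n_genes),
        )
        merged = merged[~dropped]
    out = merged[["sample_id", "gene_id", "probe_id", "dx"]].copy()
    out["dy"] = merged["intensity"] - merged["_ref"]
    return out.reset_index(drop=True)


def fit_positional_bias(
    pairs: pd.DataFrame, span: float = 0.3, iterations: int = 3
) -> BiasCurve:
    """Lowess fit of the dy-vs-dx trend.

    Locally weighted linear regression (``span`` fraction of points per local
    fit, ``iterations`` robustifying passes) evaluated on the sorted unique dx
    grid, then shifted so the offset at dx=0 is exactly 0.
    """
    if not 0 < span <= 1:
        raise FitError(f"span must be in (0, 1], got {span}")
    if len(pairs) < 10:
        raise FitError(
            f"only {len(pairs)} dx/dy pairs; pool pairs across samples to fit "
            "a stable positional-bias trend"
        )
    dx = pairs["dx"].to_numpy(dtype=float)
    dy = pairs["dy"].to_numpy(dtype=float)
    fit0 = sm.nonparametric.lowess(dy, dx, frac=span, it=0, return_sorted=False)
    scale = np.median(np.abs(dy - fit0))
    if iterations > 0 and scale > 1e-12 * max(1.0, float(np.max(np.abs(dy)))):
        with np.errstate(invalid="ignore", divide="ignore"):
            values = sm.nonparametric.lowess(
                dy, dx, frac=span, it=iterations, return_sorted=False
            )
        if not np.isfinite(values).all():
            values = fit0
    else:
        # robustifying weights degenerate when the residual scale is ~0
        # (noiseless data); the plain local fit is already exact there
        values = fit0
    support, first = np.unique(dx, return_index=True)
    offset = values[first]
    curve = BiasCurve(support=support, offset=offset - np.interp(0.0, support, offset))
    return curve


def apply_bias_correction(probes: pd.DataFrame, curve: BiasCurve) -> pd.DataFrame:
    """Subtract the fitted positional trend from log2 intensities.

    The trend is negative for 3'-distal probes, so subtracting it restores the
    attenuated signal; dx=0 probes are unchanged.
    """
    _require_columns(probes, ["dx", "intensity"])
    if "scale" in probes.columns and (probes["scale"] == "linear").any():
        raise DataError("bias correction expects log2-scale intensities")
    out = probes.copy()
    out["intensity"] = out["intensity"] - curve(out["dx"].to_numpy())
    return out


def summarize_gene_intensity(probes: pd.DataFrame) -> pd.DataFrame:
    """Median over a gene's corrected probes, per sample; genes x samples."""
    _require_columns(probes, ["sample_id", "gene_id", "intensity"])
    matrix = probes.pivot_table(
        index="gene_id", columns="sample_id", values="intensity", aggfunc="median"
    )
    matrix.index.name = "gene_id"
    matrix.columns.name = None
    return matrix


def percentile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples to their mean quantile function.

    Each column's rank-ordered values are replaced by the across-column mean
    of the values at that rank (for unequal non-missing counts, by linear
    interpolation of the mean quantile function).  Ties receive the mean of
    the reference values they span; missing entries are excluded from ranking
    and preserved as missing.
    """
    if matrix.shape[1] < 2:
        raise DataError("percentile normalization needs >= 2 samples")
    counts = matrix.notna().sum(axis=0)
    bad = counts[counts < 2]
    if len(bad):
        raise DataError(
            f"sample {bad.index[0]!r} has {int(bad.iloc[0])} non-missing values; "
            "need >= 2"
        )
    n_ref = int(counts.max())
    grid = np.linspace(0.0, 1.0, n_ref)
    ref = np.zeros(n_ref)
    for col in matrix.columns:
        vals = matrix[col].dropna().to_numpy(dtype=float)
        ref += np.quantile(vals, grid)
    ref /= matrix.shape[1]

    out = matrix.copy().astype(float)
    csum = np.concatenate([[0.0], np.cumsum(ref)])
    for col in matrix.columns:
        mask = matrix[col].notna().to_numpy()
        vals = matrix[col].to_numpy(dtype=float)[mask]
        n = vals.size
        if n == n_ref:
            targets = ref
            tsum = csum
        else:
            targets = np.interp(np.linspace(0.0, 1.0, n), grid, ref)
            tsum = np.concatenate([[0.0], np.cumsum(targets)])
        rmin = rankdata(vals, method="min").astype(int)
        rmax = rankdata(vals, method="max").astype(int)
        new = (tsum[rmax] - tsum[rmin - 1]) / (rmax - rmin + 1)
        col_out = out[col].to_numpy(dtype=float)
        col_out[mask] = new
        out[col] = col_out
    return out


def normalize_experiment(
    probes: pd.DataFrame,
    span: float = 0.3,
    pool_samples: bool = False,
    iterations: int = 3,
) -> pd.DataFrame:
    """Full probe-table -> normalized expression-matrix pipeline.

    Replicate medians, dx/dy pairing, Lowess bias fit (pooled across all genes
    within each sample, or across samples with ``pool_samples=True``), trend
    subtraction, per-gene probe medians and quantile normalization.
    """
    med = to_log2(median_over_replicates(probes))
    pairs = compute_dx_dy(med)
    if pool_samples:
        curve = fit_positional_bias(pairs, span=span, iterations=iterations)
        corrected = apply_bias_correction(med, curve)
    else:
        parts = []
        for sample, chunk in med.groupby("sample_id", sort=False):
            sample_pairs = pairs[pairs["sample_id"] == sample]
            curve = fit_positional_bias(sample_pairs, span=span, iterations=iterations)
            parts.append(apply_bias_correction(chunk, curve))
        corrected = pd.concat(parts, ignore_index=True)
    matrix = summarize_gene_intensity(corrected)
    return percentile_normalize(matrix)


def split_by_condition(matrix: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Split a matrix whose columns are ``"<strain>|<condition>"`` sample ids
    into per-condition matrices with strain-id columns."""
    out: dict[str, pd.DataFrame] = {}
    for col in matrix.columns:
        strain, _, condition = str(col).rpartition("|")
        if not strain:
            raise DataError(f"column {col!r} is not of the form strain|condition")
        out.setdefault(condition, {})[strain] = matrix[col]
    return {cond: pd.DataFrame(cols) for cond, cols in out.items()}


def compute_log_ratios(
    xylulose: pd.DataFrame, glucose: pd.DataFrame
) -> pd.DataFrame:
    """Per gene and strain, log2(xylulose) - log2(glucose) expression.

    Inputs are normalized log2 matrices with strain-id columns; strains are
    matched by id, genes by index.  Missing entries in either input propagate.
    """
    strains = [s for s in xylulose.columns if s in set(glucose.columns)]
    if not strains:
        raise DataError("no shared strains between the two condition matrices")
    genes = xylulose.index.intersection(glucose.index)
    return xylulose.loc[genes, strains] - glucose.loc[genes, strains]
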