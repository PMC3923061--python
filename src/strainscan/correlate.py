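"""Gene-group / phenotype correlation analysis.

Pearson correlation with pairwise-complete missing-data handling, the
systematic scan of all gene groups against a phenotype, per-gene
classification of pentose-phosphate-pathway genes by correlation sign and
induction, similarity of expression profiles to reference conditions, and the
quadrant rule separating ribosomal-protein-modulated from amino-acid-
biosynthesis-modulated conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError

DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class CorrelationResult:
    group: str
    phenotype: str
    r: float
    n: int
    p_value: float
    significant: bool


@dataclass(frozen=True)
class PPPGeneClass:
    gene_id: str
    correlation_class: str  # positive | negative | none
    induction_class: str  # + | - | 0


def pearson_correlation(x, y) -> tuple[float, float, int]:
    """Pearson r with a two-sided t-test p-value (n-2 df), pairwise-complete.

    Pairs with a missing value in either vector are dropped; at least 3
    complete pairs and nonzero variance on both sides are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("x and y must have the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise DataError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("correlation undefined: zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue), int(n)


def correlate_group_phenotype(
    profiles: pd.DataFrame,
    phenotypes: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
) -> list[CorrelationResult]:
    """Correlate every group profile with every phenotype column.

    ``profiles`` is groups x strains (e.g. from
    :func:`strainscan.groups.group_profiles`); ``phenotypes`` is strains x
    phenotype columns.  Strains are matched by id; each (group, phenotype)
    pair yields one :class:`CorrelationResult` flagged significant at
    ``alpha``.
    """
    strains = [s for s in profiles.columns if s in phenotypes.index]
    if len(strains) < 3:
        raise DataError("fewer than 3 strains shared between profiles and phenotypes")
    results = []
    for group in profiles.index:
        for pheno in phenotypes.columns:
            r, p, n = pearson_correlation(
                profiles.loc[group, strains].to_numpy(dtype=float),
                phenotypes.loc[strains, pheno].to_numpy(dtype=float),
            )
            results.append(
                CorrelationResult(
                    group=str(group),
                    phenotype=str(pheno),
                    r=r,
                    n=n,
                    p_value=p,
                    significant=p < alpha,
                )
            )
    return results


def scan_groups(
    profiles: pd.DataFrame,
    phenotype: pd.Series,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Systematic scan: correlate every group with one phenotype and rank.

    Returns a frame sorted by descending |r| (ties by group name) with a
    Bonferroni column for transparency and a ``top_anticorrelated`` marker on
    the single strongest significantly anti-correlated group, if any.
    """
    if len(profiles) < 1:
        raise DataError("scan needs at least one group profile")
    pheno_frame = phenotype.to_frame(name=str(phenotype.name or "phenotype"))
    results = correlate_group_phenotype(profiles, pheno_frame, alpha=alpha)
    df = pd.DataFrame(
        {
            "group": [c.group for c in results],
            "phenotype": [c.phenotype for c in results],
            "r": [c.r for c in results],
            "n": [c.n for c in results],
            "p_value": [c.p_value for c in results],
            "significant": [c.significant for c in results],
        }
    )
    df["bonferroni_significant"] = df["p_value"] < alpha / len(df)
    df["abs_r"] = df["r"].abs()
    df = (
        df.sort_values(["abs_r", "group"], ascending=[False, True])
        .drop(columns="abs_r")
        .reset_index(drop=True)
    )
    anti = df[(df["r"] < 0) & df["significant"]]
    df["top_anticorrelated"] = False
    if len(anti):
        df.loc[anti.index[0], "top_anticorrelated"] = True
    return df


def classify_ppp_gene(
    r: float,
    mean_log_diff: float,
    c_thresh: float = 0.3,
    d_thresh: float = 0.2,
    gene_id: str = "",
) -> PPPGeneClass:
    """Classify one gene by correlation sign and induction on the new sugar.

    ``positive`` if r > c_thresh, ``negative`` if r < -c_thresh, else
    ``none``; induction ``+`` if the mean log-difference exceeds d_thresh,
    ``-`` below -d_thresh, else ``0``.  Values exactly at a threshold fall in
    the neutral class.
    """
    if not -1.0 <= r <= 1.0:
        raise DataError(f"correlation must be in [-1, 1], got {r}")
    if not math.isfinite(mean_log_diff):
        raise DataError("mean_log_diff must be finite")
    if r > c_thresh:
        corr = "positive"
    elif r < -c_thresh:
        corr = "negative"
    else:
        corr = "none"
    if mean_log_diff > d_thresh:
        ind = "+"
    elif mean_log_diff < -d_thresh:
        ind = "-"
    else:
        ind = "0"
    return PPPGeneClass(gene_id=gene_id, correlation_class=corr, induction_class=ind)


def classify_genes(
    matrix: pd.DataFrame,
    log_diff: pd.DataFrame,
    phenotype: pd.Series,
    genes,
    c_thresh: float = 0.3,
    d_thresh: float = 0.2,
) -> pd.DataFrame:
    """Per-gene classification for a pathway's genes.

    For each gene present in ``matrix`` (absolute expression, genes x
    strains), correlates its profile with ``phenotype`` and averages its
    ``log_diff`` row (e.g. xylulose/glucose log ratio) over strains, then
    applies :func:`classify_ppp_gene`.
    """
    rows = []
    strains = [s for s in matrix.columns if s in phenotype.index]
    for gene in genes:
        if gene not in matrix.index:
            continue
        r, p, n = pearson_correlation(
            matrix.loc[gene, strains].to_numpy(dtype=float),
            phenotype.loc[strains].to_numpy(dtype=float),
        )
        d = float(log_diff.loc[gene].mean()) if gene in log_diff.index else float("nan")
        cls = classify_ppp_gene(r, d, c_thresh=c_thresh, d_thresh=d_thresh,
                                gene_id=str(gene))
        rows.append(
            {
                "gene_id": gene,
                "r": r,
                "p_value": p,
                "n": n,
                "mean_log_diff": d,
                "correlation_class": cls.correlation_class,
                "induction_class": cls.induction_class,
            }
        )
    if not rows:
        raise DataError("none of the requested genes are in the matrix")
    return pd.DataFrame(rows)


def profile_similarity(
    matrix: pd.DataFrame, reference_profiles: pd.DataFrame
) -> pd.DataFrame:
    """Pearson similarity of each sample to each reference condition profile.

    Both inputs are genes x columns; correlations are computed over the genes
    shared by each (sample, reference) pair after pairwise-complete deletion.
    Returns samples x references.
    """
    shared = matrix.index.intersection(reference_profiles.index)
    out = pd.DataFrame(
        index=pd.Index(matrix.columns, name="sample"),
        columns=reference_profiles.columns,
        dtype=float,
    )
    for sample in matrix.columns:
        for ref in reference_profiles.columns:
            x = matrix.loc[shared, sample].to_numpy(dtype=float)
            y = reference_profiles.loc[shared, ref].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3:
                raise DataError(
                    f"fewer than 3 shared genes between sample {sample!r} and "
                    f"reference {ref!r}"
                )
            r, _, _ = pearson_correlation(x[ok], y[ok])
            out.loc[sample, ref] = r
    return out


def classify_condition_bimodal(
    delta_rp: float, delta_aa: float, theta: float = 0.5
) -> str:
    """Quadrant rule for a condition's expression response.

    A condition is RP-modulated if only the ribosomal-protein group's mean
    log-change exceeds ``theta`` in magnitude, AA-modulated if only the
    amino-acid-biosynthesis group's does, ``both`` or ``neither`` otherwise.
    """
    if not (math.isfinite(delta_rp) and math.isfinite(delta_aa)):
        raise DataError("inputs must be finite")
    rp = abs(delta_rp) > theta
    aa = abs(delta_aa) > theta
    if rp and aa:
        return "both"
    if rp:
        return "RP-modulated"
    if aa:
        return "AA-modulated"
    return "neither"
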