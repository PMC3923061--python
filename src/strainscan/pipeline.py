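"""Pipeline orchestration: simulate -> normalize -> growth -> correlate -> report.

Every stage reads and writes plain TSV/JSON artifacts in an output directory,
logs record counts, and is skipped when its outputs already exist (unless
forced), so a run is resumable and — under a fixed seed and config —
byte-identical on rerun.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import growth, normalize
from .config import CONDITIONS, CohortConfig
from .correlate import DEFAULT_ALPHA, classify_genes, scan_groups
from .exceptions import DataError
from .groups import GeneGroupSet, filter_min_strains, group_profiles, parse_gmt, write_gmt
from .simulate import generate_cohort

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"

STAGES = ("simulate", "normalize", "growth", "correlate", "report")


@dataclass
class RunConfig:
    """Resolved parameters of a pipeline run; serialized beside its outputs."""

    outdir: str = "run"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    span: float = 0.3
    pool_samples: bool = False
    w_min: int = 5
    r2_min: float = 0.999
    k_min_strains: int = 14
    alpha: float = DEFAULT_ALPHA
    c_thresh: float = 0.3
    d_thresh: float = 0.2
    theta: float = 0.5
    ppp_group: str = "PPP"
    force: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    @classmethod
    def from_dict(cls, d) -> "RunConfig":
        d = dict(d)
        if "cohort" in d and not isinstance(d["cohort"], CohortConfig):
            d["cohort"] = CohortConfig.from_dict(d["cohort"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT, na_rep="NA")


def _read_matrix(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values="NA")


def _fresh(paths: list[Path], force: bool) -> bool:
    return force or not all(p.exists() for p in paths)


def stage_simulate(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    targets = [out / n for n in (
        "design.tsv", "probes.tsv", "phenotypes.tsv", "curves.tsv",
        "groups.gmt", "expression_true.tsv", "truth.json",
    )]
    if not _fresh(targets, cfg.force):
        logger.info("simulate: outputs present, skipping")
        return
    cohort = generate_cohort(cfg.cohort)
    _write_tsv(cohort["design"], out / "design.tsv")
    _write_tsv(cohort["probes"], out / "probes.tsv")
    _write_tsv(cohort["phenotypes"], out / "phenotypes.tsv")
    _write_tsv(cohort["curves"], out / "curves.tsv")
    _write_tsv(cohort["expression"], out / "expression_true.tsv", index=True)
    gset = GeneGroupSet()
    for name, genes in cohort["groups"].items():
        gset.add(name, genes, provenance="synthetic")
    write_gmt(gset, out / "groups.gmt")
    with open(out / "truth.json", "w") as fh:
        json.dump(cohort["truth"], fh, indent=2, sort_keys=True)
    logger.info(
        "simulate: %d probes rows, %d strains x conditions, %d curve points",
        len(cohort["probes"]), len(cohort["phenotypes"]), len(cohort["curves"]),
    )


def stage_normalize(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    targets = [out / "expr.tsv", out / "logratio.tsv"]
    if not _fresh(targets, cfg.force):
        logger.info("normalize: outputs present, skipping")
        return
    probes = pd.read_csv(out / "probes.tsv", sep="\t")
    matrix = normalize.normalize_experiment(
        probes, span=cfg.span, pool_samples=cfg.pool_samples
    )
    _write_tsv(matrix, out / "expr.tsv", index=True)
    by_cond = normalize.split_by_condition(matrix)
    for cond, m in by_cond.items():
        _write_tsv(m, out / f"expr_{cond}.tsv", index=True)
    if {"xylulose", "glucose"} <= set(by_cond):
        ratios = normalize.compute_log_ratios(by_cond["xylulose"], by_cond["glucose"])
        _write_tsv(ratios, out / "logratio.tsv", index=True)
    logger.info("normalize: %d genes x %d samples", *matrix.shape)


def stage_growth(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    target = out / "growth_fits.tsv"
    if not _fresh([target], cfg.force):
        logger.info("growth: outputs present, skipping")
        return
    curves = pd.read_csv(out / "curves.tsv", sep="\t")
    fits = growth.fit_growth_table(curves, w_min=cfg.w_min, r2_min=cfg.r2_min)
    _write_tsv(fits, target)
    logger.info("growth: fitted %d curves", len(fits))


def stage_correlate(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    targets = [out / "correlations.tsv", out / "ppp_classes.tsv"]
    if not _fresh(targets, cfg.force):
        logger.info("correlate: outputs present, skipping")
        return
    groups = parse_gmt(out / "groups.gmt")
    ratios = filter_min_strains(_read_matrix(out / "logratio.tsv"), k=cfg.k_min_strains)
    fits = pd.read_csv(out / "growth_fits.tsv", sep="\t")
    phen = pd.read_csv(out / "phenotypes.tsv", sep="\t")

    xyl = fits[fits["condition"] == "xylulose"].set_index("strain_id")
    rate = xyl["growth_rate"].rename("growth_rate_xylulose")
    xyl_abs = filter_min_strains(
        _read_matrix(out / "expr_xylulose.tsv"), k=cfg.k_min_strains
    )
    # scan both expression modes: xylulose/glucose log-ratios and absolute
    # xylulose levels
    scans = []
    for mode, matrix in (("logratio", ratios), ("absolute_xylulose", xyl_abs)):
        scan = scan_groups(group_profiles(matrix, groups), rate, alpha=cfg.alpha)
        scan.insert(0, "mode", mode)
        scans.append(scan)
    scan = pd.concat(scans, ignore_index=True)
    _write_tsv(scan, out / "correlations.tsv")

    # per-gene PPP classification: absolute xylulose levels vs ethanol yield
    ethanol = (
        phen[phen["condition"] == "xylulose"]
        .set_index("strain_id")["ethanol"]
    )
    try:
        ppp = classify_genes(
            xyl_abs, ratios, ethanol, groups[cfg.ppp_group],
            c_thresh=cfg.c_thresh, d_thresh=cfg.d_thresh,
        )
    except (KeyError, DataError) as exc:
        logger.warning("PPP classification skipped: %s", exc)
        ppp = pd.DataFrame(
            columns=["gene_id", "r", "p_value", "n", "mean_log_diff",
                     "correlation_class", "induction_class"]
        )
    _write_tsv(ppp, out / "ppp_classes.tsv")
    logger.info("correlate: %d group correlations, %d PPP genes", len(scan), len(ppp))


def stage_report(cfg: RunConfig) -> None:
    out = Path(cfg.outdir)
    target = out / "summary.json"
    if not _fresh([target], cfg.force):
        logger.info("report: outputs present, skipping")
        return
    fits = pd.read_csv(out / "growth_fits.tsv", sep="\t")
    scan = pd.read_csv(out / "correlations.tsv", sep="\t")
    dispersions = {}
    for cond in CONDITIONS:
        rates = fits.loc[fits["condition"] == cond, "growth_rate"]
        if len(rates) >= 2:
            dispersions[cond] = growth.cohort_dispersion(rates)
    if "mode" in scan.columns and (scan["mode"] == "absolute_xylulose").any():
        primary = scan[scan["mode"] == "absolute_xylulose"]
    else:
        primary = scan
    top = primary.head(5)[["group", "phenotype", "r", "p_value", "significant"]]
    anti = primary[primary.get("top_anticorrelated", False) == True]  # noqa: E712
    ppp = pd.read_csv(out / "ppp_classes.tsv", sep="\t")
    summary = {
        "growth_rate_dispersion": dispersions,
        "top_correlations": top.to_dict(orient="records"),
        "top_anticorrelated_group": (
            anti.iloc[0]["group"] if len(anti) else None
        ),
        "ppp_class_counts": (
            ppp.groupby(["correlation_class", "induction_class"])
            .size()
            .rename("count")
            .reset_index()
            .to_dict(orient="records")
            if len(ppp)
            else []
        ),
        "n_growth_fits": int(len(fits)),
    }
    with open(target, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("report: wrote %s", target)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "normalize": stage_normalize,
    "growth": stage_growth,
    "correlate": stage_correlate,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig, stages=STAGES) -> Path:
    """Run the requested stages in order; returns the output directory.

    The resolved configuration is written beside the outputs; a stage failure
    aborts the run with the stage name and cause.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
    for stage in STAGES:
        if stage not in stages:
            continue
        try:
            _STAGE_FUNCS[stage](cfg)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    return out
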