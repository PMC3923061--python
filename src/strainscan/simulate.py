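"""Synthetic cohort generator with known ground truth.

Emulates the data structure of a two-species yeast strain collection profiled
on custom two-color 60K arrays and phenotyped in a plate reader:

* an array design with 3-4 probes per gene, each printed 3-4 times, and a
  3'-positional intensity bias that decays with distance from the gene's
  3'-most probe (``P_last``);
* per-strain phenotypes (growth rate, doubling time, ethanol yield) whose
  inter-strain dispersion differs by carbon source;
* a true log2 expression matrix in which the *mean* expression of chosen gene
  groups is coupled to chosen phenotypes at an exact target Pearson rho;
* probe-level intensities derived from the true expression plus positional
  bias, probe offsets and replicate noise;
* three-phase growth curves (lag / exponential / saturation) sampled every
  30 minutes with multiplicative noise.

Every artifact is a deterministic function of ``(config, config.seed)``; each
generator stage draws from its own child stream of the root seed so that
stages can be regenerated independently.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CONDITIONS, SPECIES, CohortConfig
from .exceptions import ConfigurationError, DataError

_STAGE_IDS = {
    "design": 0,
    "phenotypes": 1,
    "expression": 2,
    "probes": 3,
    "curves": 4,
}

PROBE_TABLE_COLUMNS = [
    "sample_id",
    "strain_id",
    "condition",
    "gene_id",
    "probe_id",
    "placement_index",
    "dx",
    "intensity",
    "scale",
]


def _stage_rng(config: CohortConfig, stage: str) -> np.random.Generator:
    seq = np.random.SeedSequence(config.seed, spawn_key=(_STAGE_IDS[stage],))
    return np.random.default_rng(seq)


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size) -> np.ndarray:
    """Log-normal sample with the given arithmetic mean and std/mean ratio."""
    if cv < 0:
        raise ConfigurationError("CV must be >= 0")
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    if sigma2 == 0.0:
        return np.full(size, mean, dtype=float)
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=size)


def gene_ids(config: CohortConfig) -> list[str]:
    width = max(4, len(str(config.n_genes - 1)))
    return [f"g{i:0{width}d}" for i in range(config.n_genes)]


def gene_group_map(config: CohortConfig) -> dict[str, list[str]]:
    """Deterministic gene-group membership: consecutive blocks from gene 0."""
    ids = gene_ids(config)
    groups: dict[str, list[str]] = {}
    start = 0
    for name, size in config.group_sizes.items():
        groups[name] = ids[start : start + size]
        start += size
    return groups


def strain_ids(config: CohortConfig) -> dict[str, list[str]]:
    out = {}
    for sp in SPECIES:
        out[sp] = [f"{sp[:3]}{i + 1:02d}" for i in range(config.n_strains_per_species)]
    return out


def sample_id(strain: str, condition: str) -> str:
    return f"{strain}|{condition}"


def split_sample_id(sample: str) -> tuple[str, str]:
    strain, _, condition = sample.rpartition("|")
    return strain, condition


# ---------------------------------------------------------------------------
# array design


def generate_array_design(config: CohortConfig) -> pd.DataFrame:
    """Draw the probe layout: 3-4 probes per gene, each placed 3-4 times.

    Returns a frame with columns ``gene_id, probe_id, dx, n_placements``.
    Exactly one probe per gene sits at ``dx = 0`` (the gene's 3'-most probe,
    P_last); the rest get distinct positive distances up to ``max_dx``.
    """
    if config.n_genes < 1:
        raise ConfigurationError("n_genes must be >= 1")
    rng = _stage_rng(config, "design")
    rows = []
    for gene in gene_ids(config):
        n_probes = int(rng.integers(3, 5))
        others = rng.choice(
            np.arange(1, config.max_dx + 1), size=n_probes - 1, replace=False
        )
        dxs = np.concatenate([[0], np.sort(others)])
        for j, dx in enumerate(dxs):
            rows.append(
                {
                    "gene_id": gene,
                    "probe_id": f"{gene}_p{j}",
                    "dx": int(dx),
                    "n_placements": int(rng.integers(3, 5)),
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "probe_id", "dx", "n_placements"])


# ---------------------------------------------------------------------------
# phenotypes


def generate_cohort_phenotypes(config: CohortConfig) -> pd.DataFrame:
    """Draw per-strain, per-condition phenotypes.

    Growth rates and ethanol yields are log-normal with the configured
    per-condition mean and CV; doubling time is ln(2)/rate.  Returns one row
    per strain x condition with columns
    ``strain_id, species, condition, growth_rate, doubling_time, ethanol``.
    """
    rng = _stage_rng(config, "phenotypes")
    ids = strain_ids(config)
    frames = []
    for condition in CONDITIONS:
        gr_mean = config.growth_rate_mean[condition]
        gr_cv = config.growth_rate_cv[condition]
        if gr_mean <= 0:
            raise ConfigurationError("growth_rate_mean must be > 0")
        eth_mean = config.ethanol_mean[condition]
        eth_cv = config.ethanol_cv[condition]
        for sp in SPECIES:
            n = len(ids[sp])
            rates = _lognormal(rng, gr_mean, gr_cv, n)
            ethanol = _lognormal(rng, eth_mean, eth_cv, n)
            frames.append(
                pd.DataFrame(
                    {
                        "strain_id": ids[sp],
                        "species": sp,
                        "condition": condition,
                        "growth_rate": rates,
                        "doubling_time": np.log(2) / rates,
                        "ethanol": ethanol,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# expression


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def generate_expression(
    config: CohortConfig, phenotypes: pd.DataFrame
) -> pd.DataFrame:
    """Construct the true gene x sample log2 expression matrix.

    For each gene group and condition the group's per-strain *mean* expression
    is built as ``rho * z + sqrt(1 - rho^2) * eps`` where ``z`` is the
    standardized coupled phenotype across strains and ``eps`` is independent
    standard normal, then scaled by ``expression_noise_sd``; with no coupling
    configured, ``rho = 0`` and the group mean is pure noise.  Per-gene
    deviations within a group are centered per strain, so the realized group
    mean equals the constructed signal exactly and the expected Pearson
    correlation between group mean and phenotype equals ``rho``.  Ungrouped
    genes are independent noise around a per-gene baseline.

    Columns are sample ids of the form ``"<strain>|<condition>"``.
    """
    rng = _stage_rng(config, "expression")
    genes = gene_ids(config)
    groups = gene_group_map(config)
    gene_index = {g: i for i, g in enumerate(genes)}
    sd = config.expression_noise_sd

    for group, phenotype, condition in config.coupling:
        if group not in groups:
            raise ConfigurationError(f"coupling refers to unknown group {group!r}")

    baseline = rng.uniform(6.0, 12.0, size=config.n_genes)

    columns: list[str] = []
    blocks: list[np.ndarray] = []
    for condition in CONDITIONS:
        pheno = (
            phenotypes[phenotypes["condition"] == condition]
            .drop_duplicates("strain_id")
            .set_index("strain_id")
        )
        strains = list(pheno.index)
        n = len(strains)
        mat = np.empty((config.n_genes, n))
        grouped = np.zeros(config.n_genes, dtype=bool)
        for name, members in groups.items():
            rho = 0.0
            for (g, p, c), r in config.coupling.items():
                if g == name and c == condition:
                    rho = r
                    z = _standardize(pheno[p].to_numpy(dtype=float))
                    break
            else:
                z = np.zeros(n)
            eps = rng.standard_normal(n)
            signal = sd * (rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * eps)
            idx = np.array([gene_index[g] for g in members])
            scatter = sd * rng.standard_normal((len(idx), n))
            scatter -= scatter.mean(axis=0, keepdims=True)  # group mean == signal
            mat[idx, :] = baseline[idx, None] + signal[None, :] + scatter
            grouped[idx] = True
        free = ~grouped
        mat[free, :] = baseline[free, None] + sd * rng.standard_normal(
            (int(free.sum()), n)
        )
        blocks.append(mat)
        columns.extend(sample_id(s, condition) for s in strains)

    return pd.DataFrame(np.hstack(blocks), index=pd.Index(genes, name="gene_id"),
                        columns=columns)


# ---------------------------------------------------------------------------
# probe intensities


def positional_bias(dx: np.ndarray, max_dx: int, amplitude: float) -> np.ndarray:
    """Linear 3' attenuation: 0 at dx=0, `amplitude` log2 at the largest dx."""
    if max_dx <= 0:
        return np.zeros_like(np.asarray(dx, dtype=float))
    return amplitude * np.asarray(dx, dtype=float) / float(max_dx)


def generate_probe_intensities(
    expr: pd.DataFrame, design: pd.DataFrame, config: CohortConfig
) -> pd.DataFrame:
    """Expand true expression into a long-form probe-placement table.

    Each placement's log2 intensity is
    ``expression - bias(dx) + probe_offset + replicate_noise`` with a fixed
    offset per probe (probe-sequence effect, sd ``probe_noise_sd``) and i.i.d.
    per-placement noise (sd ``replicate_noise_sd``).  Intensities are emitted
    on the linear scale, as a scanner would report them.
    """
    missing = set(expr.index) - set(design["gene_id"])
    if missing:
        raise DataError(
            f"{len(missing)} genes in the expression matrix are absent from "
            f"the array design (e.g. {sorted(missing)[:3]})"
        )
    rng = _stage_rng(config, "probes")
    design = design[design["gene_id"].isin(expr.index)].reset_index(drop=True)

    probe_offset = rng.normal(0.0, config.probe_noise_sd, size=len(design))
    max_dx = int(design["dx"].max())
    bias = positional_bias(design["dx"].to_numpy(), max_dx, config.bias_amplitude)

    # one row per placement
    reps = design["n_placements"].to_numpy()
    row_idx = np.repeat(np.arange(len(design)), reps)
    placement = np.concatenate([np.arange(1, r + 1) for r in reps])

    samples = list(expr.columns)
    gene_rows = expr.loc[design["gene_id"].to_numpy()].to_numpy()  # probes x samples
    base = gene_rows - bias[:, None] + probe_offset[:, None]
    base = base[row_idx, :]  # placements x samples
    noise = rng.normal(0.0, config.replicate_noise_sd, size=base.shape)
    log2_int = base + noise

    n_rows = len(row_idx)
    n_samples = len(samples)
    strains, conditions = zip(*(split_sample_id(s) for s in samples))
    table = pd.DataFrame(
        {
            "sample_id": np.repeat(samples, n_rows),
            "strain_id": np.repeat(strains, n_rows),
            "condition": np.repeat(conditions, n_rows),
            "gene_id": np.tile(design["gene_id"].to_numpy()[row_idx], n_samples),
            "probe_id": np.tile(design["probe_id"].to_numpy()[row_idx], n_samples),
            "placement_index": np.tile(placement, n_samples),
            "dx": np.tile(design["dx"].to_numpy()[row_idx], n_samples),
            "intensity": np.exp2(log2_int.T.ravel()),
            "scale": "linear",
        }
    )
    return table[PROBE_TABLE_COLUMNS]


# ---------------------------------------------------------------------------
# growth curves


def growth_curve_od(
    t: np.ndarray,
    rate: float,
    od0: float,
    od_sat: float,
    lag: float,
) -> np.ndarray:
    """Three-phase deterministic curve: lag, exponential at `rate`, plateau."""
    od = od0 * np.exp(rate * np.clip(t - lag, 0.0, None))
    return np.minimum(od, od_sat)


def generate_growth_curves(
    phenotypes: pd.DataFrame, config: CohortConfig
) -> pd.DataFrame:
    """Simulate plate-reader OD time series for every strain x condition.

    Long-form output: ``strain_id, condition, time_h, od``.  Each reading is
    the three-phase curve times log-normal noise with CV ``od_noise_cv``.
    """
    if (phenotypes["growth_rate"] <= 0).any():
        raise DataError("growth_rate must be > 0 for curve simulation")
    rng = _stage_rng(config, "curves")
    t = np.arange(
        0.0, config.duration_hours + 1e-9, config.sampling_interval_hours
    )
    frames = []
    for row in phenotypes.itertuples(index=False):
        od = growth_curve_od(
            t, row.growth_rate, config.od_initial, config.od_saturation,
            config.lag_hours,
        )
        noise = _lognormal(rng, 1.0, config.od_noise_cv, t.size)
        frames.append(
            pd.DataFrame(
                {
                    "strain_id": row.strain_id,
                    "condition": row.condition,
                    "time_h": t,
                    "od": od * noise,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# whole cohort


def generate_cohort(config: CohortConfig) -> dict:
    """Generate every artifact of a synthetic study.

    Returns a dict with ``design``, ``phenotypes``, ``expression``,
    ``probes``, ``curves``, ``groups`` (gene-group membership) and ``truth``
    (the configured couplings and distribution parameters, for recovery
    checks).
    """
    design = generate_array_design(config)
    phenotypes = generate_cohort_phenotypes(config)
    expression = generate_expression(config, phenotypes)
    probes = generate_probe_intensities(expression, design, config)
    curves = generate_growth_curves(phenotypes, config)
    truth = {
        "seed": config.seed,
        "coupling": [
            {"group": g, "phenotype": p, "condition": c, "rho": rho}
            for (g, p, c), rho in config.coupling.items()
        ],
        "growth_rate_mean": dict(config.growth_rate_mean),
        "growth_rate_cv": dict(config.growth_rate_cv),
        "bias_amplitude": config.bias_amplitude,
    }
    return {
        "design": design,
        "phenotypes": phenotypes,
        "expression": expression,
        "probes": probes,
        "curves": curves,
        "groups": gene_group_map(config),
        "truth": truth,
    }
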