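"""Monte-Carlo recovery experiments on synthetic cohorts.

These routines generate many independent cohorts from a configured ground
truth and push them through the analysis stages, so that a configured
coupling, dispersion or null rate can be compared with what the pipeline
recovers.  They are used both by the test suite and by the reproduction
script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CohortConfig
from .correlate import correlate_group_phenotype, scan_groups
from .groups import group_profiles
from .growth import cohort_dispersion, fit_growth_table
from .normalize import split_by_condition
from .simulate import (
    gene_group_map,
    generate_cohort_phenotypes,
    generate_expression,
    generate_growth_curves,
)


def derive_seeds(base_seed: int, n: int) -> np.ndarray:
    """Expand one root seed into ``n`` independent 31-bit cohort seeds."""
    rng = np.random.default_rng(base_seed)
    return rng.integers(1, 2**31 - 1, size=n)


def recover_coupling_once(
    config: CohortConfig, group: str, phenotype: str, condition: str
) -> float:
    """Generate one cohort and recover the group/phenotype Pearson r.

    Uses the true expression matrix of the coupled condition: group mean
    profile (per strain) correlated against the phenotype across strains.
    """
    phen = generate_cohort_phenotypes(config)
    expr = generate_expression(config, phen)
    cond_matrix = split_by_condition(expr)[condition]
    groups = gene_group_map(config)
    profiles = group_profiles(cond_matrix, {group: groups[group]})
    pheno_table = (
        phen[phen["condition"] == condition]
        .set_index("strain_id")[[phenotype]]
    )
    (result,) = correlate_group_phenotype(profiles, pheno_table)
    return result.r


def recover_coupling(
    rho: float,
    n_strains_per_species: int = 12,
    group: str = "AA",
    phenotype: str = "growth_rate",
    condition: str = "xylulose",
    n_seeds: int = 200,
    base_seed: int = 1,
    n_genes: int = 400,
) -> np.ndarray:
    """Recovered r for ``n_seeds`` independent cohorts with coupling ``rho``."""
    seeds = derive_seeds(base_seed, n_seeds)
    out = np.empty(n_seeds)
    base = CohortConfig(
        n_strains_per_species=n_strains_per_species,
        n_genes=n_genes,
        group_sizes={group: 60},
        coupling={(group, phenotype, condition): rho},
    )
    for i, seed in enumerate(seeds):
        out[i] = recover_coupling_once(
            base.replace(seed=int(seed)), group, phenotype, condition
        )
    return out


def recover_growth_dispersion(
    cv: float,
    condition: str,
    n_strains_per_species: int = 12,
    od_noise_cv: float = 0.02,
    n_seeds: int = 200,
    base_seed: int = 1,
) -> np.ndarray:
    """Estimated std/mean of fitted growth rates, one value per cohort.

    Per seed: draw 2 x ``n_strains_per_species`` true rates at the configured
    CV, simulate OD curves at 30-minute sampling with multiplicative noise,
    fit every curve log-linearly and take the cohort dispersion of the
    estimates.
    """
    seeds = derive_seeds(base_seed, n_seeds)
    out = np.empty(n_seeds)
    for i, seed in enumerate(seeds):
        cfg = CohortConfig(
            n_strains_per_species=n_strains_per_species,
            n_genes=1,
            group_sizes={},
            coupling={},
            growth_rate_cv={"glucose": cv, "xylulose": cv},
            od_noise_cv=od_noise_cv,
            seed=int(seed),
        )
        phen = generate_cohort_phenotypes(cfg)
        phen = phen[phen["condition"] == condition]
        curves = generate_growth_curves(phen, cfg)
        fits = fit_growth_table(curves)
        out[i] = cohort_dispersion(fits["growth_rate"].to_numpy())
    return out


def null_scan_hit(config: CohortConfig, phenotype: str, condition: str,
                  alpha: float) -> bool:
    """One null cohort: does the group scan flag any significant group?"""
    phen = generate_cohort_phenotypes(config)
    expr = generate_expression(config, phen)
    cond_matrix = split_by_condition(expr)[condition]
    profiles = group_profiles(cond_matrix, gene_group_map(config))
    pheno = phen[phen["condition"] == condition].set_index("strain_id")[phenotype]
    scan = scan_groups(profiles, pheno, alpha=alpha)
    return bool(scan["significant"].any())


def null_scan_rate(
    n_cohorts: int = 500,
    n_groups: int = 10,
    alpha: float = 0.01,
    n_strains_per_species: int = 12,
    base_seed: int = 1,
) -> float:
    """Family-wise false-positive rate of the scan with all couplings zero."""
    seeds = derive_seeds(base_seed, n_cohorts)
    sizes = {f"grp{i:02d}": 15 for i in range(n_groups)}
    base = CohortConfig(
        n_strains_per_species=n_strains_per_species,
        n_genes=15 * n_groups,
        group_sizes=sizes,
        coupling={},
    )
    hits = 0
    for seed in seeds:
        hits += null_scan_hit(
            base.replace(seed=int(seed)), "growth_rate", "xylulose", alpha
        )
    return hits / n_cohorts
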