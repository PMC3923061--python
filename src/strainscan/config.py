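"""Cohort configuration: the ground truth a synthetic study is generated from.

A :class:`CohortConfig` fully parameterizes the simulator — array geometry,
strain phenotype distributions per carbon source, gene-group sizes, the
couplings between group mean expression and phenotypes, and every noise
amplitude.  Together with its ``seed`` it determines every generated artifact
exactly, which is what makes downstream parameter-recovery tests possible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .exceptions import ConfigurationError

CONDITIONS = ("glucose", "xylulose")
SPECIES = ("cerevisiae", "paradoxus")
PHENOTYPES = ("growth_rate", "doubling_time", "ethanol")

#: Default gene-group sizes.  The categories mirror the functional modules a
#: yeast carbon-source study tracks: ribosomal proteins (RP), ribosome
#: biogenesis (Ribi), the two environmental-stress-response arms, amino-acid
#: biosynthesis / Gcn4 regulon (AA), the proteasome, glycolysis+fermentation
#: (GF), pentose phosphate pathway (PPP), TCA cycle and respiratory chain (RC).
#: Sizes are scaled-down but order-of-magnitude realistic for a 2000-gene
#: simulated genome.
DEFAULT_GROUP_SIZES: dict[str, int] = {
    "RP": 60,
    "Ribi": 80,
    "ESR_induced": 100,
    "ESR_repressed": 100,
    "AA": 60,
    "proteasome": 30,
    "GF": 30,
    "PPP": 15,
    "TCA": 20,
    "RC": 40,
}

#: Default coupling between the amino-acid biosynthesis group's mean
#: expression and growth rate on xylulose (Pearson rho).  All other
#: group/phenotype pairs default to zero coupling.
DEFAULT_COUPLING: dict[tuple[str, str, str], float] = {
    ("AA", "growth_rate", "xylulose"): -0.79,
}


def _as_coupling_key(entry: Mapping) -> tuple[tuple[str, str, str], float]:
    key = (str(entry["group"]), str(entry["phenotype"]), str(entry["condition"]))
    return key, float(entry["rho"])


@dataclass
class CohortConfig:
    """Full parameterization of a synthetic strain cohort.

    Parameters
    ----------
    n_strains_per_species
        Strains per species; the cohort holds twice this many strains
        (*S. cerevisiae* plus *S. paradoxus*), each grown on both carbon
        sources.
    n_genes
        Genes on the simulated genome.  Gene-group members are assigned from
        the front; the remainder are ungrouped background genes.
    group_sizes
        Gene count per named group.  Groups must fit inside ``n_genes``.
    growth_rate_mean, growth_rate_cv
        Per-condition log-normal parameters of the true specific growth rate
        (1/h) across strains.  The defaults encode fast, uniform growth on
        glucose and slow, dispersed growth on xylulose.
    ethanol_mean, ethanol_cv
        Per-condition ethanol yield (fraction of the theoretical maximum) and
        its inter-strain coefficient of variation.
    coupling
        Map ``(group, phenotype, condition) -> rho``: the target Pearson
        correlation between the group's per-strain mean expression in that
        condition and the phenotype.  At most one coupling per
        (group, condition).
    bias_amplitude
        Total 3'-positional intensity attenuation, in log2 units, between a
        gene's 3'-most probe and the probe farthest from it.
    replicate_noise_sd, probe_noise_sd, expression_noise_sd
        Log2-scale noise: per-placement replicate noise, fixed per-probe
        offsets, and the spread of true expression across strains.
    od_noise_cv
        Multiplicative (log-normal) noise on each optical-density reading.
    od_initial, od_saturation, lag_hours, duration_hours, sampling_interval_hours
        Growth-curve shape: inoculum OD, carrying capacity, lag phase and the
        sampling grid (default 30-minute reads over 48 h).
    max_dx
        Largest possible probe distance (bp) from the 3'-most probe.
    seed
        Root seed; every artifact is a pure function of (config, seed).
    """

    n_strains_per_species: int = 12
    n_genes: int = 2000
    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    growth_rate_mean: dict[str, float] = field(
        default_factory=lambda: {"glucose": 0.45, "xylulose": 0.15}
    )
    growth_rate_cv: dict[str, float] = field(
        default_factory=lambda: {"glucose": 0.13, "xylulose": 0.29}
    )
    ethanol_mean: dict[str, float] = field(
        default_factory=lambda: {"glucose": 0.90, "xylulose": 0.50}
    )
    ethanol_cv: dict[str, float] = field(
        default_factory=lambda: {"glucose": 0.05, "xylulose": 0.35}
    )
    coupling: dict[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING)
    )
    bias_amplitude: float = 1.0
    replicate_noise_sd: float = 0.10
    probe_noise_sd: float = 0.25
    expression_noise_sd: float = 0.50
    od_noise_cv: float = 0.02
    od_initial: float = 0.05
    od_saturation: float = 1.5
    lag_hours: float = 2.0
    duration_hours: float = 48.0
    sampling_interval_hours: float = 0.5
    max_dx: int = 900
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        if self.n_strains_per_species < 1:
            raise ConfigurationError("n_strains_per_species must be >= 1")
        if sum(self.group_sizes.values()) > self.n_genes:
            raise ConfigurationError(
                "group sizes exceed n_genes "
                f"({sum(self.group_sizes.values())} > {self.n_genes})"
            )
        for name, size in self.group_sizes.items():
            if size < 1:
                raise ConfigurationError(f"group {name!r} has non-positive size")
        for cond in CONDITIONS:
            if self.growth_rate_mean.get(cond, 1.0) <= 0:
                raise ConfigurationError(f"growth_rate_mean[{cond}] must be > 0")
        for cvs in (self.growth_rate_cv, self.ethanol_cv):
            for cond, cv in cvs.items():
                if cv < 0:
                    raise ConfigurationError(f"CV for {cond} must be >= 0")
        for (group, phenotype, condition), rho in self.coupling.items():
            if group not in self.group_sizes:
                raise ConfigurationError(f"coupling refers to unknown group {group!r}")
            if phenotype not in PHENOTYPES:
                raise ConfigurationError(
                    f"coupling refers to unknown phenotype {phenotype!r}"
                )
            if condition not in CONDITIONS:
                raise ConfigurationError(
                    f"coupling refers to unknown condition {condition!r}"
                )
            if abs(rho) > 1:
                raise ConfigurationError(f"|rho| must be <= 1, got {rho}")
        seen: set[tuple[str, str]] = set()
        for group, _, condition in self.coupling:
            if (group, condition) in seen:
                raise ConfigurationError(
                    f"multiple couplings for group {group!r} in {condition!r}"
                )
            seen.add((group, condition))
        for sd in (
            self.replicate_noise_sd,
            self.probe_noise_sd,
            self.expression_noise_sd,
            self.od_noise_cv,
            self.bias_amplitude,
        ):
            if sd < 0:
                raise ConfigurationError("noise amplitudes must be >= 0")
        if self.od_initial <= 0 or self.od_saturation <= self.od_initial:
            raise ConfigurationError("require 0 < od_initial < od_saturation")
        if self.sampling_interval_hours <= 0 or self.duration_hours <= 0:
            raise ConfigurationError("sampling grid must be positive")
        if self.max_dx < 1:
            raise ConfigurationError("max_dx must be >= 1")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["coupling"] = [
            {"group": g, "phenotype": p, "condition": c, "rho": rho}
            for (g, p, c), rho in self.coupling.items()
        ]
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        raw = d.pop("coupling", None)
        if raw is not None:
            if isinstance(raw, Mapping):
                coupling = {tuple(k): float(v) for k, v in raw.items()}
            else:
                coupling = dict(_as_coupling_key(e) for e in raw)
            d["coupling"] = coupling
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def replace(self, **kwargs) -> "CohortConfig":
        return dataclasses.replace(self, **kwargs)
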