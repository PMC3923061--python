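"""Gene-group definitions, missingness filtering and group mean profiles."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)


@dataclass
class GeneGroupSet:
    """Named gene lists with per-group provenance, insertion-ordered."""

    groups: dict[str, list[str]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, genes, provenance: str = "") -> None:
        seen: set[str] = set()
        unique = [g for g in genes if not (g in seen or seen.add(g))]
        if not unique:
            raise DataError(f"group {name!r} has no genes")
        self.groups[name] = unique
        self.provenance[name] = provenance

    def __getitem__(self, name: str) -> list[str]:
        return self.groups[name]

    def __contains__(self, name: str) -> bool:
        return name in self.groups

    def __iter__(self):
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    def items(self):
        return self.groups.items()


def parse_gmt(path) -> GeneGroupSet:
    """Read gene sets from a GMT file (name, description, genes; tab-separated).

    Duplicate genes within a line are collapsed; group order is preserved.
    """
    out = GeneGroupSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}: line {lineno}: GMT lines need name, description "
                    f"and at least one gene ({len(fields)} fields found)"
                )
            name, description = fields[0], fields[1]
            genes = [g for g in fields[2:] if g]
            out.add(name, genes, provenance=description)
    if len(out) == 0:
        logger.warning("GMT file %s contained no gene sets", path)
    return out


def write_gmt(groups: GeneGroupSet | dict, path) -> None:
    with open(path, "w") as fh:
        items = groups.items() if hasattr(groups, "items") else groups
        for name, genes in items:
            desc = ""
            if isinstance(groups, GeneGroupSet):
                desc = groups.provenance.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def filter_min_strains(matrix: pd.DataFrame, k: int = 14) -> pd.DataFrame:
    """Drop genes measured in fewer than ``k`` strains.

    Keeps rows with at least ``k`` non-missing values — genes with data from
    fewer strains are omitted from group summaries.
    """
    if k < 1:
        raise ConfigurationError(f"k must be >= 1, got {k}")
    keep = matrix.notna().sum(axis=1) >= k
    return matrix.loc[keep]


def group_mean_profile(matrix: pd.DataFrame, genes, name: str = "") -> pd.Series:
    """Per-strain mean expression over a group's genes present in the matrix.

    Missing entries are excluded per strain; a strain with no data for any
    group gene is missing in the profile.
    """
    unique = list(dict.fromkeys(genes))
    present = matrix.index.intersection(unique)
    if len(present) == 0:
        raise DataError(f"no genes of group {name or '<unnamed>'!r} are in the matrix")
    return matrix.loc[present].mean(axis=0, skipna=True)


def group_profiles(matrix: pd.DataFrame, groups: GeneGroupSet | dict) -> pd.DataFrame:
    """Stack group mean profiles into a groups x strains frame.

    Groups with no genes in the matrix are skipped with a warning rather than
    aborting the scan.
    """
    items = groups.items() if hasattr(groups, "items") else groups
    rows = {}
    for name, genes in items:
        try:
            rows[name] = group_mean_profile(matrix, genes, name=name)
        except DataError:
            logger.warning("group %r has no genes in the matrix; skipped", name)
    if not rows:
        raise DataError("no group has any gene in the matrix")
    out = pd.DataFrame(rows).T
    out.index.name = "group"
    return out
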