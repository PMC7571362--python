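"""Cause hierarchy, nature-of-injury registry and demographic grid.

The cause hierarchy is the external-cause tree (road injuries, falls,
self-harm, ...) on which both the fatal and non-fatal pipelines operate.
Nodes carry age restrictions (e.g. self-harm cannot occur in the early
neonatal age group) and flags saying whether mortality and/or morbidity are
estimated for the cause.  The nature registry holds the 47 bodily-injury
outcomes (fractures, burns, spinal-cord lesions, ...) with their short- and
long-term disability weights.  The demographic grid defines the
location / age / sex / year cells every surface is estimated on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import StructuralError, ValidationError

SEXES = ("male", "female")

# default estimation period: 28 years, 1990-2017 inclusive
DEFAULT_YEARS = range(1990, 2018)


def _bundled(name: str) -> Path:
    return Path(str(resources.files("microgbd.data").joinpath(name)))


# ---------------------------------------------------------------------------
# Cause hierarchy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CauseNode:
    cause_id: str
    name: str
    level: int
    parent_id: str | None
    fatal_estimated: bool
    nonfatal_estimated: bool
    excluded_age_groups: frozenset[str] = field(default_factory=frozenset)
    icd9_codes: tuple[str, ...] = ()   # verbatim metadata, never parsed
    icd10_codes: tuple[str, ...] = ()


class CauseHierarchy:
    """Validated tree of :class:`CauseNode` objects."""

    def __init__(self, nodes: list[CauseNode]):
        self.nodes: dict[str, CauseNode] = {}
        for node in nodes:
            if node.cause_id in self.nodes:
                raise ValidationError(f"duplicate cause_id {node.cause_id!r}")
            self.nodes[node.cause_id] = node
        self._validate()
        self._children: dict[str, list[str]] = {cid: [] for cid in self.nodes}
        for node in self.nodes.values():
            if node.parent_id is not None:
                self._children[node.parent_id].append(node.cause_id)

    def _validate(self) -> None:
        roots = [n for n in self.nodes.values() if n.parent_id is None]
        if len(roots) != 1:
            raise StructuralError(f"expected exactly one root, found {len(roots)}")
        for node in self.nodes.values():
            if node.parent_id is not None and node.parent_id not in self.nodes:
                raise StructuralError(
                    f"cause {node.cause_id!r} has dangling parent {node.parent_id!r}"
                )
        # cycle check: walk to the root from every node
        for node in self.nodes.values():
            seen = {node.cause_id}
            cur = node
            while cur.parent_id is not None:
                if cur.parent_id in seen:
                    raise StructuralError(f"cycle through {cur.parent_id!r}")
                seen.add(cur.parent_id)
                cur = self.nodes[cur.parent_id]

    # -- structure ---------------------------------------------------------

    @property
    def root(self) -> CauseNode:
        return next(n for n in self.nodes.values() if n.parent_id is None)

    def __getitem__(self, cause_id: str) -> CauseNode:
        try:
            return self.nodes[cause_id]
        except KeyError:
            raise KeyError(f"unknown cause_id {cause_id!r}") from None

    def __contains__(self, cause_id: str) -> bool:
        return cause_id in self.nodes

    def children(self, cause_id: str) -> list[CauseNode]:
        return [self.nodes[c] for c in self._children[cause_id]]

    def ancestors(self, cause_id: str) -> list[CauseNode]:
        out, cur = [], self[cause_id]
        while cur.parent_id is not None:
            cur = self.nodes[cur.parent_id]
            out.append(cur)
        return out

    def levels(self) -> list[int]:
        return sorted({n.level for n in self.nodes.values()})

    def at_level(self, level: int) -> list[CauseNode]:
        return [n for n in self.nodes.values() if n.level == level]

    def estimated_causes(self) -> list[CauseNode]:
        """Causes actually estimated: every node below the group level
        (level >= 2).  The root and the level-1 groups are aggregates."""
        return [n for n in self.nodes.values() if n.level >= 2]

    def fatal_causes(self) -> list[CauseNode]:
        return [n for n in self.estimated_causes() if n.fatal_estimated]

    def nonfatal_causes(self) -> list[CauseNode]:
        return [n for n in self.estimated_causes() if n.nonfatal_estimated]

    # -- restrictions ------------------------------------------------------

    def is_allowed(self, cause_id: str, age_group_id: str, sex: str | None = None) -> bool:
        """Whether a cause is permitted in a demographic cell.  Restrictions
        inherit down the tree; no injury cause carries a sex restriction."""
        if sex is not None and sex not in SEXES:
            raise ValidationError(f"unknown sex {sex!r}")
        node = self[cause_id]
        if age_group_id in node.excluded_age_groups:
            return False
        return all(
            age_group_id not in anc.excluded_age_groups for anc in self.ancestors(cause_id)
        )

    # -- I/O ---------------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for n in self.nodes.values():
            rows.append({
                "cause_id": n.cause_id,
                "name": n.name,
                "level": n.level,
                "parent_id": "" if n.parent_id is None else n.parent_id,
                "fatal_estimated": int(n.fatal_estimated),
                "nonfatal_estimated": int(n.nonfatal_estimated),
                "excluded_age_groups": ";".join(sorted(n.excluded_age_groups)),
                "icd9_codes": "; ".join(n.icd9_codes),
                "icd10_codes": "; ".join(n.icd10_codes),
            })
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_cause_hierarchy(config: str | Path | None = None) -> CauseHierarchy:
    """Load and validate the cause tree (bundled registry by default)."""
    path = _bundled("causes.csv") if config is None else Path(config)
    df = pd.read_csv(path, dtype=str).fillna("")
    nodes = []
    for _, r in df.iterrows():
        nodes.append(CauseNode(
            cause_id=r["cause_id"],
            name=r["name"],
            level=int(r["level"]),
            parent_id=r["parent_id"] or None,
            fatal_estimated=bool(int(r["fatal_estimated"])),
            nonfatal_estimated=bool(int(r["nonfatal_estimated"])),
            excluded_age_groups=frozenset(
                x for x in r["excluded_age_groups"].split(";") if x
            ),
            icd9_codes=tuple(s.strip() for s in r["icd9_codes"].split(";") if s.strip()),
            icd10_codes=tuple(s.strip() for s in r["icd10_codes"].split(";") if s.strip()),
        ))
    return CauseHierarchy(nodes)


# ---------------------------------------------------------------------------
# Nature registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NatureCategory:
    nature_id: str
    name: str
    dw_short: float | None        # None iff long-term only (amputations)
    dw_long: float | None         # None iff no long-term disability
    long_term_only: bool
    no_long_term: bool
    p_long_default: float

    def __post_init__(self):
        for dw, label in ((self.dw_short, "dw_short"), (self.dw_long, "dw_long")):
            if dw is not None and not (0.0 <= dw <= 1.0):
                raise ValidationError(f"{self.nature_id}: {label}={dw} outside [0,1]")
        if (self.dw_short is None) != self.long_term_only:
            raise ValidationError(
                f"{self.nature_id}: dw_short must be absent iff long_term_only"
            )
        if (self.dw_long is None) != self.no_long_term:
            raise ValidationError(
                f"{self.nature_id}: dw_long must be absent iff no_long_term"
            )
        if self.long_term_only and self.p_long_default != 1.0:
            raise ValidationError(f"{self.nature_id}: long-term only requires p_long=1")
        if self.no_long_term and self.p_long_default != 0.0:
            raise ValidationError(f"{self.nature_id}: no long term requires p_long=0")
        if not (0.0 <= self.p_long_default <= 1.0):
            raise ValidationError(f"{self.nature_id}: p_long outside [0,1]")


class NatureRegistry:
    def __init__(self, categories: list[NatureCategory]):
        self.categories: dict[str, NatureCategory] = {}
        for cat in categories:
            if cat.nature_id in self.categories:
                raise ValidationError(f"duplicate nature_id {cat.nature_id!r}")
            self.categories[cat.nature_id] = cat
        self._by_name = {c.name: c for c in categories}

    def __len__(self) -> int:
        return len(self.categories)

    def __iter__(self):
        return iter(self.categories.values())

    def __contains__(self, nature_id: str) -> bool:
        return nature_id in self.categories

    def ids(self) -> list[str]:
        return list(self.categories)

    def get(self, key: str) -> NatureCategory:
        """Look up by id or by display name."""
        if key in self.categories:
            return self.categories[key]
        if key in self._by_name:
            return self._by_name[key]
        raise KeyError(f"unknown nature {key!r}")

    def dw_short(self, key: str) -> float | None:
        return self.get(key).dw_short

    def dw_long(self, key: str) -> float | None:
        return self.get(key).dw_long

    def p_long(self, key: str) -> float:
        return self.get(key).p_long_default

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.categories.values():
            rows.append({
                "nature_id": c.nature_id, "name": c.name,
                "dw_short": "" if c.dw_short is None else f"{c.dw_short:.4f}",
                "dw_long": "" if c.dw_long is None else f"{c.dw_long:.4f}",
                "long_term_only": int(c.long_term_only),
                "no_long_term": int(c.no_long_term),
                "p_long_default": c.p_long_default,
            })
        return pd.DataFrame(rows)

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_nature_registry(config: str | Path | None = None) -> NatureRegistry:
    path = _bundled("natures.csv") if config is None else Path(config)
    df = pd.read_csv(path, dtype=str).fillna("")
    cats = []
    for _, r in df.iterrows():
        cats.append(NatureCategory(
            nature_id=r["nature_id"],
            name=r["name"],
            dw_short=float(r["dw_short"]) if r["dw_short"] != "" else None,
            dw_long=float(r["dw_long"]) if r["dw_long"] != "" else None,
            long_term_only=bool(int(r["long_term_only"])),
            no_long_term=bool(int(r["no_long_term"])),
            p_long_default=float(r["p_long_default"]),
        ))
    return NatureRegistry(cats)


# ---------------------------------------------------------------------------
# Demographic grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AgeGroup:
    """Half-open age interval [start, end) in years."""
    age_group_id: str
    name: str
    age_start: float
    age_end: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.age_start + self.age_end)


@dataclass(frozen=True)
class Location:
    location_id: str
    level: int                      # 0 super-region, 1 region, 2 country
    parent_id: str | None


class DemographicGrid:
    """Location hierarchy x age groups x sexes x years, with populations.

    ``populations`` is indexed by (location_id, year, age_group_id, sex) and
    must be strictly positive for country-level cells; aggregate locations
    get the sum of their children.
    """

    def __init__(self, locations: list[Location], age_groups: list[AgeGroup],
                 years: range, populations: pd.DataFrame):
        self.locations = {loc.location_id: loc for loc in locations}
        self.age_groups = list(age_groups)
        self.years = list(years)
        self.sexes = list(SEXES)
        self._check_age_groups()
        self.countries = [l.location_id for l in locations if l.level == 2]
        pops = populations.set_index(["location_id", "year", "age_group_id", "sex"])[
            "population"
        ]
        if (pops <= 0).any():
            raise ValidationError("population must be strictly positive")
        self._pop = pops
        self._aggregate_populations()

    def _check_age_groups(self) -> None:
        ags = sorted(self.age_groups, key=lambda a: a.age_start)
        for a, b in zip(ags, ags[1:]):
            if not math.isclose(a.age_end, b.age_start, rel_tol=1e-9):
                raise ValidationError(
                    f"age groups not contiguous: {a.age_group_id} ends {a.age_end}, "
                    f"{b.age_group_id} starts {b.age_start}"
                )
        self.age_groups = ags

    def _aggregate_populations(self) -> None:
        # parent population = sum over children, computed bottom-up
        for level in (1, 0):
            for loc in self.locations.values():
                if loc.level != level:
                    continue
                kids = [l.location_id for l in self.locations.values()
                        if l.parent_id == loc.location_id]
                total = sum(
                    (self._pop.xs(k, level="location_id") for k in kids),
                    start=0,
                )
                total = pd.concat({loc.location_id: total}, names=["location_id"])
                self._pop = pd.concat([self._pop, total])

    def age_group(self, age_group_id: str) -> AgeGroup:
        for ag in self.age_groups:
            if ag.age_group_id == age_group_id:
                return ag
        raise KeyError(f"unknown age_group_id {age_group_id!r}")

    def population(self, location_id: str, year: int, age_group_id: str, sex: str) -> float:
        return float(self._pop.loc[(location_id, year, age_group_id, sex)])

    def population_frame(self) -> pd.DataFrame:
        return self._pop.reset_index()

    def country_cells(self) -> pd.DataFrame:
        """All (country, year, age group, sex) estimation cells."""
        idx = pd.MultiIndex.from_product(
            [self.countries, self.years,
             [a.age_group_id for a in self.age_groups], self.sexes],
            names=["location_id", "year", "age_group_id", "sex"],
        )
        return idx.to_frame(index=False)

    def children_of(self, location_id: str) -> list[str]:
        return [l.location_id for l in self.locations.values()
                if l.parent_id == location_id]


def default_age_groups(config: str | Path | None = None) -> list[AgeGroup]:
    path = _bundled("age_groups.csv") if config is None else Path(config)
    df = pd.read_csv(path)
    return [AgeGroup(r.age_group_id, r["name"], float(r.age_start), float(r.age_end))
            for _, r in df.iterrows()]


# ---------------------------------------------------------------------------
# Combinatorics of multiple injuries
# ---------------------------------------------------------------------------

def count_injury_permutations(n: int) -> int:
    """Number of ordered arrangements (n!) of n distinct natures of injury.

    A single injury event can produce several bodily injuries whose severity
    ordering matters for attributing disability; with only 10 candidate
    natures there are already 10! = 3,628,800 orderings, which is why this
    pipeline (like the estimation framework it mirrors) models only the
    single most disabling nature per case.
    """
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool) or n < 1:
        raise ValidationError(f"n must be a positive integer, got {n!r}")
    return math.factorial(int(n))
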