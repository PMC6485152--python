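"""Synthetic taxonomies and patient cohorts with controlled subpopulation structure.

No clinical dataset ships with this package, so every experiment runs on
generated data. Two generators cover that need:

* :func:`gen_taxonomy` — a full regular tree of a requested depth and
  branching, with readable path-string codes (``C1``, ``C1.2``, ...).
* :func:`gen_cohort` — a four-stratum cohort on the age × HLOS plane. Each
  stratum draws a ``core_fraction`` share of every patient's codes from its
  own core pool (by default the leaves of one dedicated chapter, disjoint
  between strata) and the rest from a background pool shared by all strata.
  This two-pool mixture is the simplest structure that reproduces the
  qualitative phenomena of interest: separable strata at high core share,
  exchangeable strata at zero, and prototype dilution as the prototype size
  outgrows the core pool.

Stratum sizes default to 283/82/257/83 patients (young-short / young-long /
old-short / old-long); codes per patient follow a truncated Poisson with
mean 4 (min 1). All randomness flows through one seeded generator per call.

The TOY5 fixture — an 11-node, 5-level hand-checkable taxonomy — also lives
here; every worked example in the test suite is computed on it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .prototype import DEFAULT_STRATA, PatientRecord, SubpopulationSpec
from .taxonomy import ROOT_CODE, Taxonomy

__all__ = [
    "TOY5_EDGES",
    "toy5",
    "TaxonomyGenSpec",
    "gen_taxonomy",
    "CohortGenSpec",
    "gen_cohort",
    "split_cohort",
]

_MAX_NODES = 100_000

#: (child, parent) edges of the TOY5 fixture. Leaves: A1a1, A1a2, A1b, A2a, B1a.
#: A2a is a level-3 leaf; the deepest chain root→A→A1→A1a→A1a1 has 5 levels.
TOY5_EDGES: tuple[tuple[str, str], ...] = (
    ("A", "root"),
    ("B", "root"),
    ("A1", "A"),
    ("A2a", "A"),
    ("B1", "B"),
    ("A1a", "A1"),
    ("A1b", "A1"),
    ("B1a", "B1"),
    ("A1a1", "A1a"),
    ("A1a2", "A1a"),
)


def toy5() -> Taxonomy:
    """The 11-node, 5-level hand-checkable fixture taxonomy."""
    return Taxonomy(dict(TOY5_EDGES), "root")


@dataclass(frozen=True)
class TaxonomyGenSpec:
    """Shape of a generated taxonomy: depth and per-level branching factors."""

    levels: int
    branching: tuple[int, ...]
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "branching", tuple(self.branching))
        if self.levels < 2:
            raise ConfigurationError("a taxonomy needs at least 2 levels")
        if len(self.branching) != self.levels - 1:
            raise ConfigurationError(
                f"branching must list {self.levels - 1} factors for {self.levels} levels"
            )
        if any(b < 1 for b in self.branching):
            raise ConfigurationError("branching factors must be >= 1")
        nodes = 1
        width = 1
        for b in self.branching:
            width *= b
            nodes += width
        if nodes > _MAX_NODES:
            raise ConfigurationError(f"taxonomy would have {nodes} nodes (guard: {_MAX_NODES})")


def gen_taxonomy(spec: TaxonomyGenSpec) -> Taxonomy:
    """Full regular tree per the spec; codes are path strings like ``C2.1.3``."""
    parent_of: dict[str, str] = {}
    frontier = [ROOT_CODE]
    for level, b in enumerate(spec.branching):
        nxt = []
        for parent in frontier:
            stem = "C" if parent == ROOT_CODE else parent + "."
            for i in range(1, b + 1):
                child = f"{stem}{i}"
                parent_of[child] = parent
                nxt.append(child)
        frontier = nxt
    return Taxonomy(parent_of, ROOT_CODE)


def _default_pools(taxonomy: Taxonomy) -> tuple[dict[str, tuple[str, ...]], tuple[str, ...]]:
    """One disjoint chapter of leaves per stratum; remaining chapters shared."""
    chapters = sorted(taxonomy.children_of(taxonomy.root))
    labels = [s.label for s in DEFAULT_STRATA]
    if len(chapters) <= len(labels):
        raise ConfigurationError(
            f"need more than {len(labels)} root branches for default pools, "
            f"got {len(chapters)}"
        )

    def leaves_under(node: str) -> tuple[str, ...]:
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            kids = taxonomy.children_of(n)
            if kids:
                stack.extend(kids)
            else:
                out.append(n)
        return tuple(sorted(out))

    cores = {label: leaves_under(ch) for label, ch in zip(labels, chapters)}
    background = tuple(
        leaf for ch in chapters[len(labels):] for leaf in leaves_under(ch)
    )
    return cores, background


@dataclass(frozen=True)
class CohortGenSpec:
    """Sampling recipe for a four-stratum synthetic cohort.

    ``stratum_pools`` maps stratum labels to their core code pools;
    ``background`` is shared by every stratum. ``core_fraction`` is the share
    of each patient's codes drawn from their stratum's core pool (1.0 means
    fully disjoint strata, 0.0 means exchangeable strata).
    """

    stratum_pools: Mapping[str, tuple[str, ...]]
    background: tuple[str, ...]
    n_per_stratum: Mapping[str, int] = field(
        default_factory=lambda: {
            "young_short": 283, "young_long": 82, "old_short": 257, "old_long": 83,
        }
    )
    codes_per_patient_mean: float = 4.0
    core_fraction: float = 0.7
    strata: tuple[SubpopulationSpec, ...] = DEFAULT_STRATA
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ConfigurationError("core_fraction must lie in [0, 1]")
        if self.codes_per_patient_mean < 1.0:
            raise ConfigurationError("codes_per_patient_mean must be >= 1")
        labels = {s.label for s in self.strata}
        if set(self.n_per_stratum) - labels or set(self.stratum_pools) - labels:
            raise ConfigurationError("stratum labels must match the strata specs")

    @classmethod
    def default(cls, taxonomy: Taxonomy, *, seed: int = 0, core_fraction: float = 0.7,
                **kwargs) -> "CohortGenSpec":
        """Default pools: one disjoint root branch per stratum + shared background."""
        cores, background = _default_pools(taxonomy)
        return cls(stratum_pools=cores, background=background, seed=seed,
                   core_fraction=core_fraction, **kwargs)


def _truncated_poisson(rng: np.random.Generator, mean: float) -> int:
    while True:  # rejection keeps the min-1 support without shifting the shape
        n = int(rng.poisson(mean))
        if n >= 1:
            return n


def gen_cohort(taxonomy: Taxonomy, spec: CohortGenSpec) -> list[PatientRecord]:
    """Sample the cohort; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    patients: list[PatientRecord] = []
    max_age = 90  # sampling cap for open-ended elderly strata
    for stratum in spec.strata:
        n_patients = spec.n_per_stratum.get(stratum.label, 0)
        core = list(spec.stratum_pools.get(stratum.label, ()))
        background = list(spec.background)
        for i in range(n_patients):
            n_codes = _truncated_poisson(rng, spec.codes_per_patient_mean)
            n_core = int(round(spec.core_fraction * n_codes))
            n_bg = n_codes - n_core
            if n_core > len(core) or n_bg > len(background):
                raise ConfigurationError(
                    f"stratum {stratum.label!r}: pool too small for {n_codes} codes "
                    f"({n_core} core of {len(core)}, {n_bg} background of {len(background)})"
                )
            codes: list[str] = []
            if n_core:
                codes += list(rng.choice(core, size=n_core, replace=False))
            if n_bg:
                codes += list(rng.choice(background, size=n_bg, replace=False))
            age = int(rng.integers(stratum.age_min, min(stratum.age_max, max_age) + 1))
            hlos = int(rng.integers(stratum.hlos_min, stratum.hlos_max + 1))
            patients.append(PatientRecord(f"{stratum.label}-{i:04d}", age, hlos,
                                          frozenset(codes)))
    return patients


def split_cohort(
    patients: Sequence[PatientRecord],
    train_fraction: float,
    seed: int,
) -> tuple[list[PatientRecord], list[PatientRecord]]:
    """Deterministic train/test split stratified by (age stratum × HLOS class)."""
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    groups: dict[tuple[str, str], list[PatientRecord]] = {}
    for p in patients:
        key = ("young" if p.age <= 50 else "old", "short" if p.hlos <= 18 else "long")
        groups.setdefault(key, []).append(p)
    train: list[PatientRecord] = []
    test: list[PatientRecord] = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda p: p.patient_id)
        if len(members) < 2:
            warnings.warn(f"stratum {key} has {len(members)} patient(s); all go to train")
            train += members
            continue
        order = rng.permutation(len(members))
        n_train = int(round(train_fraction * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train += [members[i] for i in order[:n_train]]
        test += [members[i] for i in order[n_train:]]
    return train, test
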