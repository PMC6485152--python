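"""Subpopulation prototypes: ranked core diagnoses of a patient stratum.

Patients are stratified on the age × hospital-length-of-stay (HLOS) plane.
Within one stratum, every distinct diagnosis code d* receives a prototype
score — the sum of its code-level distances to every diagnosis occurrence d
in the stratum::

    prototype_score(d*) = Σ_{d ∈ D} CS(d*, d)

where D is by default the *multiset* of all occurrences, so frequent codes
pull the centre of mass toward themselves. Codes are ranked ascending by
score (smallest summed distance = most central = most prototypical) and the
prototype is the top-k ranked codes.

Prototype separation — how distinguishable two strata's prototypes are at a
given size k — is the all-pairs mean distance between the two top-k code
sets; the area under the separation-vs-k curve summarizes a CS method's
ability to keep prototypes apart across sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Sequence

import numpy as np

from .concept_distance import CSMethod, concept_distance
from .errors import ConfigurationError, DomainError, UnknownCodeError
from .information_content import ICMethod
from .set_distance import ss_allpairs_avg
from .taxonomy import Taxonomy

__all__ = [
    "PatientRecord",
    "SubpopulationSpec",
    "Prototype",
    "DEFAULT_STRATA",
    "stratify",
    "prototype_score",
    "build_prototype",
    "prototype_separation",
    "separation_auc",
]


@dataclass(frozen=True)
class PatientRecord:
    """One patient: id, age (years), HLOS (days), and the set of diagnosis codes."""

    patient_id: str
    age: int
    hlos: int
    codes: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "codes", frozenset(self.codes))
        if not self.codes:
            raise DomainError(f"patient {self.patient_id!r} has no diagnosis codes")
        if self.hlos < 1:
            raise DomainError(f"patient {self.patient_id!r} has HLOS {self.hlos} < 1 day")
        if self.age < 0:
            raise DomainError(f"patient {self.patient_id!r} has negative age")


@dataclass(frozen=True)
class SubpopulationSpec:
    """A rectangle on the age × HLOS plane with a label."""

    label: str
    age_min: int
    age_max: int
    hlos_min: int
    hlos_max: int

    def __post_init__(self):
        if self.age_min > self.age_max or self.hlos_min > self.hlos_max:
            raise ConfigurationError(f"spec {self.label!r}: min exceeds max")

    def contains(self, patient: PatientRecord) -> bool:
        return (self.age_min <= patient.age <= self.age_max
                and self.hlos_min <= patient.hlos <= self.hlos_max)

    def overlaps(self, other: "SubpopulationSpec") -> bool:
        return (self.age_min <= other.age_max and other.age_min <= self.age_max
                and self.hlos_min <= other.hlos_max and other.hlos_min <= self.hlos_max)


#: The four predefined strata: 18–50 vs ≥51 years crossed with HLOS 1–18 vs 19–50 days.
DEFAULT_STRATA: tuple[SubpopulationSpec, ...] = (
    SubpopulationSpec("young_short", 18, 50, 1, 18),
    SubpopulationSpec("young_long", 18, 50, 19, 50),
    SubpopulationSpec("old_short", 51, 120, 1, 18),
    SubpopulationSpec("old_long", 51, 120, 19, 50),
)


@dataclass(frozen=True)
class Prototype:
    """Ranked (code, prototype score) list for one stratum, most central first."""

    label: str
    ranked_codes: tuple[tuple[str, float], ...]
    source_spec: SubpopulationSpec | None = field(default=None, compare=False)

    def top_k(self, k: int) -> list[str]:
        """The codes of the k most central entries (all, if fewer exist)."""
        if k < 1:
            raise DomainError(f"prototype size k must be >= 1, got {k}")
        return [code for code, _ in self.ranked_codes[:k]]

    def __len__(self) -> int:
        return len(self.ranked_codes)


def stratify(
    patients: Iterable[PatientRecord],
    specs: Sequence[SubpopulationSpec] = DEFAULT_STRATA,
) -> dict[str, list[PatientRecord]]:
    """Assign each patient to the unique matching stratum; non-matching patients are dropped.

    Specs must be pairwise disjoint on the age × HLOS plane.
    """
    for i, s in enumerate(specs):
        for other in specs[i + 1:]:
            if s.overlaps(other):
                raise ConfigurationError(f"strata {s.label!r} and {other.label!r} overlap")
    out: dict[str, list[PatientRecord]] = {s.label: [] for s in specs}
    for p in patients:
        for s in specs:
            if s.contains(p):
                out[s.label].append(p)
                break
    return out


def prototype_score(
    taxonomy: Taxonomy,
    ic_method: ICMethod | str,
    cs: CSMethod | str,
    d_star: str,
    D: Iterable[str],
) -> float:
    """Sum of code-level distances from ``d_star`` to every occurrence in ``D``.

    ``D`` is a multiset: repeated occurrences contribute repeatedly, so a
    self-occurrence contributes CS(d*, d*) each time it appears.
    """
    counts = Counter(D)
    if not counts:
        raise DomainError("prototype score undefined for an empty diagnosis multiset")
    if d_star not in taxonomy:
        raise UnknownCodeError(f"unknown concept code {d_star!r}")
    return sum(
        n * concept_distance(taxonomy, ic_method, cs, d_star, d) for d, n in counts.items()
    )


def build_prototype(
    taxonomy: Taxonomy,
    ic_method: ICMethod | str,
    cs: CSMethod | str,
    patients: Iterable[PatientRecord],
    spec: SubpopulationSpec,
    k: int,
    *,
    distinct: bool = False,
) -> Prototype:
    """Score every distinct code of the stratum and keep the k most central.

    With ``distinct=True``, D is the set of distinct codes rather than the
    occurrence multiset, so frequency no longer weights centrality. Ties in
    score are broken lexicographically by code, making the ranking
    deterministic and patient-order invariant.
    """
    if k < 1:
        raise DomainError(f"prototype size k must be >= 1, got {k}")
    stratum = [p for p in patients if spec.contains(p)]
    if not stratum:
        raise DomainError(f"stratum {spec.label!r} is empty; cannot build a prototype")
    occurrences: Counter[str] = Counter()
    for p in stratum:
        occurrences.update(p.codes)
    D = list(occurrences) if distinct else list(occurrences.elements())
    scored = [
        (code, prototype_score(taxonomy, ic_method, cs, code, D))
        for code in occurrences
    ]
    scored.sort(key=lambda item: (item[1], item[0]))
    return Prototype(spec.label, tuple(scored[:k]), spec)


def prototype_separation(
    taxonomy: Taxonomy,
    ic_method: ICMethod | str,
    cs: CSMethod | str,
    proto_a: Prototype,
    proto_b: Prototype,
    k: int,
) -> float:
    """All-pairs mean distance between the two prototypes' top-k code sets.

    Larger values mean the prototypes are more distinctly separated.
    """
    if k > len(proto_a) or k > len(proto_b):
        raise DomainError(
            f"k={k} exceeds a prototype length ({len(proto_a)}, {len(proto_b)})"
        )
    return ss_allpairs_avg(taxonomy, ic_method, cs, proto_a.top_k(k), proto_b.top_k(k))


def separation_auc(curve: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under a separation-vs-prototype-size curve."""
    if len(curve) < 2:
        raise DomainError("separation AUC needs at least two (k, separation) points")
    ks = np.asarray([p[0] for p in curve], dtype=float)
    if not np.all(np.diff(ks) > 0):
        raise DomainError("k values must be strictly increasing")
    ys = np.asarray([p[1] for p in curve], dtype=float)
    return float(np.trapezoid(ys, ks))
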