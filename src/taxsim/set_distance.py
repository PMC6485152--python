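"""Distances between two sets of taxonomy concepts (the patient level).

Eight set-level (SS) measures. The first four act on exact-match overlap
only; the remaining four aggregate code-level (CS) distances:

* ``dice`` / ``jaccard`` / ``cosine`` / ``overlap`` — one minus the classical
  overlap coefficients.
* ``closest_pair``  — the mean, over every element of both sets, of the
  distance to its closest counterpart in the other set.
* ``nonshared_avg`` — Girardi-style: elements shared by both sets contribute
  nothing; each non-shared element contributes its mean distance to the
  whole other set, normalized by |A ∪ B|.
* ``allpairs_avg``  — the plain mean over the full |A|×|B| Cartesian product.
* ``bipartite``     — minimum weighted bipartite matching: the Hungarian
  (Kuhn–Munkres) assignment minimizing the summed distance of min(|A|,|B|)
  one-to-one pairs, normalized by the number of matched edges. Surplus codes
  of the larger set are deliberately ignored, so a small set matched inside
  a large one can stay close even when the average measures are diluted.

Sets must be non-empty and must not contain the virtual root; duplicate
codes are collapsed before any computation.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
from scipy.optimize import linear_sum_assignment

from .concept_distance import CSMethod, concept_distance
from .errors import ConfigurationError, DomainError
from .information_content import ICMethod
from .taxonomy import Taxonomy

__all__ = [
    "SSMethod",
    "ss_overlap_family",
    "ss_closest_pair",
    "ss_nonshared_avg",
    "ss_allpairs_avg",
    "hungarian_min_matching",
    "ss_bipartite",
    "set_distance",
]


class SSMethod(str, Enum):
    """Choice of set-level distance (the SS slot of a ⟨IC,CS,SS⟩ triple)."""

    DICE = "dice"
    JACCARD = "jaccard"
    COSINE = "cosine"
    OVERLAP = "overlap"
    CLOSEST_PAIR = "closest_pair"
    NONSHARED_AVG = "nonshared_avg"
    ALLPAIRS_AVG = "allpairs_avg"
    BIPARTITE = "bipartite"

    @classmethod
    def parse(cls, value: "SSMethod | str") -> "SSMethod":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise ConfigurationError(
                f"unknown SS method {value!r}; expected one of {[m.value for m in cls]}"
            ) from None

    @property
    def needs_cs(self) -> bool:
        """Whether the measure aggregates code-level distances (vs binary overlap)."""
        return self in (
            SSMethod.CLOSEST_PAIR,
            SSMethod.NONSHARED_AVG,
            SSMethod.ALLPAIRS_AVG,
            SSMethod.BIPARTITE,
        )


def _as_set(codes, taxonomy: Taxonomy | None, name: str) -> frozenset[str]:
    s = frozenset(codes)
    if not s:
        raise DomainError(f"set {name} is empty; set distances are undefined for empty sets")
    if taxonomy is not None:
        if taxonomy.root in s:
            raise DomainError(f"set {name} contains the virtual root {taxonomy.root!r}")
        unknown = sorted(c for c in s if c not in taxonomy)
        if unknown:
            raise DomainError(f"set {name} contains codes not in the taxonomy: {unknown}")
    return s


def ss_overlap_family(method: SSMethod | str, A, B) -> float:
    """Dice/Jaccard/Cosine/Overlap distance on exact-match set overlap."""
    method = SSMethod.parse(method)
    A = _as_set(A, None, "A")
    B = _as_set(B, None, "B")
    inter = len(A & B)
    if method is SSMethod.DICE:
        return 1.0 - 2.0 * inter / (len(A) + len(B))
    if method is SSMethod.JACCARD:
        return 1.0 - inter / len(A | B)
    if method is SSMethod.COSINE:
        return 1.0 - inter / float(np.sqrt(len(A) * len(B)))
    if method is SSMethod.OVERLAP:
        return 1.0 - inter / min(len(A), len(B))
    raise ConfigurationError(f"{method.value} is not an overlap-family method")


def _cost_matrix(taxonomy, ic_method, cs, A, B) -> tuple[list[str], list[str], np.ndarray]:
    a_codes, b_codes = sorted(A), sorted(B)
    cost = np.empty((len(a_codes), len(b_codes)))
    for i, a in enumerate(a_codes):
        for j, b in enumerate(b_codes):
            cost[i, j] = concept_distance(taxonomy, ic_method, cs, a, b)
    return a_codes, b_codes, cost


def ss_closest_pair(taxonomy: Taxonomy, ic_method: ICMethod | str, cs: CSMethod | str,
                    A, B) -> float:
    """Mean over both sets of each element's distance to its closest counterpart."""
    A = _as_set(A, taxonomy, "A")
    B = _as_set(B, taxonomy, "B")
    _, _, cost = _cost_matrix(taxonomy, ic_method, cs, A, B)
    return float((cost.min(axis=1).sum() + cost.min(axis=0).sum()) / (len(A) + len(B)))


def ss_nonshared_avg(taxonomy: Taxonomy, ic_method: ICMethod | str, cs: CSMethod | str,
                     A, B) -> float:
    """Mean distance of non-shared elements to the whole other set, over |A ∪ B|."""
    A = _as_set(A, taxonomy, "A")
    B = _as_set(B, taxonomy, "B")
    a_codes, b_codes, cost = _cost_matrix(taxonomy, ic_method, cs, A, B)
    only_a = [i for i, a in enumerate(a_codes) if a not in B]
    only_b = [j for j, b in enumerate(b_codes) if b not in A]
    total = cost[only_a, :].mean(axis=1).sum() if only_a else 0.0
    total += cost[:, only_b].mean(axis=0).sum() if only_b else 0.0
    return float(total / len(A | B))


def ss_allpairs_avg(taxonomy: Taxonomy, ic_method: ICMethod | str, cs: CSMethod | str,
                    A, B) -> float:
    """Arithmetic mean of the distance over the full |A|×|B| Cartesian product."""
    A = _as_set(A, taxonomy, "A")
    B = _as_set(B, taxonomy, "B")
    _, _, cost = _cost_matrix(taxonomy, ic_method, cs, A, B)
    return float(cost.mean())


def hungarian_min_matching(cost) -> tuple[list[tuple[int, int]], float]:
    """Minimum-weight one-to-one assignment on a (possibly rectangular) cost matrix.

    Returns the matched (row, col) pairs — min(n_rows, n_cols) of them, each
    row and column used at most once — and the minimized total cost. Any
    cost-optimal matching may be returned; only the total is contractual.
    """
    cost = np.asarray(cost, dtype=float)
    if cost.ndim != 2 or cost.size == 0:
        raise DomainError("cost matrix must be 2-D and non-empty")
    if not np.all(np.isfinite(cost)):
        raise DomainError("cost matrix contains non-finite entries")
    rows, cols = linear_sum_assignment(cost)
    return list(zip(rows.tolist(), cols.tolist())), float(cost[rows, cols].sum())


def ss_bipartite(taxonomy: Taxonomy, ic_method: ICMethod | str, cs: CSMethod | str,
                 A, B) -> float:
    """Minimum weighted bipartite matching distance, normalized per matched edge."""
    A = _as_set(A, taxonomy, "A")
    B = _as_set(B, taxonomy, "B")
    _, _, cost = _cost_matrix(taxonomy, ic_method, cs, A, B)
    _, total = hungarian_min_matching(cost)
    return total / min(len(A), len(B))


def set_distance(
    taxonomy: Taxonomy,
    ic_method: ICMethod | str | None,
    cs: CSMethod | str | None,
    ss: SSMethod | str,
    A,
    B,
) -> float:
    """Dispatch to the selected SS measure.

    The overlap-family measures ignore ``ic_method`` and ``cs`` (they act on
    exact-match overlap only); the CS-aggregating measures require both.
    """
    ss = SSMethod.parse(ss)
    if not ss.needs_cs:
        return ss_overlap_family(ss, A, B)
    if ic_method is None or cs is None:
        raise ConfigurationError(f"SS method {ss.value!r} requires an IC and a CS method")
    fn = {
        SSMethod.CLOSEST_PAIR: ss_closest_pair,
        SSMethod.NONSHARED_AVG: ss_nonshared_avg,
        SSMethod.ALLPAIRS_AVG: ss_allpairs_avg,
        SSMethod.BIPARTITE: ss_bipartite,
    }[ss]
    return fn(taxonomy, ic_method, cs, A, B)
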