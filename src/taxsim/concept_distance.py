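"""Pairwise code-level distances between two taxonomy concepts.

The literature states these measures as "similarities", yet each formula
returns 0 for maximal resemblance, so this package uniformly calls them
distances. Notation: ``a``, ``b`` are the compared concepts, ``c`` their
least common ancestor, and ``IC(l)`` the information content of a
deepest-level node.

Four measures:

* ``binary``      — 0 iff the codes are equal, else 1.
* ``wu``          — the Wu–Palmer-style IC ratio ``1 − 2·IC(c)/(IC(a)+IC(b))``.
* ``li``          — Li's two-parameter form
  ``1 − exp(−α·(IC(a)+IC(b)−2·IC(c))) · tanh(β·IC(c))`` with benchmark
  defaults α = 0.2, β = 0.6. Note the decaying exponent: the factor shrinks
  as the concepts separate from their LCA, keeping the distance in [0, 1].
  A consequence worth knowing: ``li(a, a) = 1 − tanh(β·IC(a))`` is *not*
  zero at identity — that is a property of the formula, not a bug.
* ``simplified``  — ``(IC(l) − IC(c)) / IC(l)``, the deepest-level
  simplification of ``wu``; ``IC(l)`` is taken as the maximum IC over all
  nodes, which reduces to the total level count L under path IC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .errors import ConfigurationError, DomainError
from .information_content import ICMethod, ic
from .taxonomy import Taxonomy

__all__ = [
    "CSMethod",
    "cs_binary",
    "cs_wu",
    "cs_li",
    "cs_simplified",
    "concept_distance",
]

DEFAULT_ALPHA = 0.2
DEFAULT_BETA = 0.6
_CS_IDS = ("binary", "wu", "li", "simplified")


@dataclass(frozen=True)
class CSMethod:
    """Choice of code-level distance (the CS slot of a ⟨IC,CS,SS⟩ triple).

    ``alpha`` and ``beta`` are meaningful only for ``li``; they scale the
    contribution of concept separation and of the LCA depth respectively.
    """

    method_id: str
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA

    def __post_init__(self):
        if self.method_id not in _CS_IDS:
            raise ConfigurationError(
                f"unknown CS method {self.method_id!r}; expected one of {list(_CS_IDS)}"
            )
        if self.method_id == "li" and (self.alpha <= 0 or self.beta <= 0):
            raise ConfigurationError("cs li requires alpha > 0 and beta > 0")

    @classmethod
    def parse(cls, value: "CSMethod | str", *, alpha: float = DEFAULT_ALPHA,
              beta: float = DEFAULT_BETA) -> "CSMethod":
        if isinstance(value, cls):
            return value
        return cls(value, alpha=alpha, beta=beta)


def cs_binary(a: str, b: str) -> float:
    """0 if the codes are identical (case-sensitive), else 1."""
    return 0.0 if a == b else 1.0


def cs_wu(taxonomy: Taxonomy, ic_method: ICMethod | str, a: str, b: str) -> float:
    """IC-ratio distance ``1 − 2·IC(c)/(IC(a)+IC(b))`` with c = lca(a, b)."""
    c = taxonomy.lca(a, b)
    denom = ic(taxonomy, a, ic_method) + ic(taxonomy, b, ic_method)
    if denom == 0.0:
        # Only reachable when a = b = root under ontology IC; identity wins,
        # but the virtual root should not appear in concept sets.
        warnings.warn(
            "cs_wu evaluated at the virtual root under ontology IC; "
            "exclude the root from concept sets",
            stacklevel=2,
        )
        return 0.0
    return 1.0 - 2.0 * ic(taxonomy, c, ic_method) / denom


def cs_li(
    taxonomy: Taxonomy,
    ic_method: ICMethod | str,
    a: str,
    b: str,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
) -> float:
    """Li's distance ``1 − exp(−α·Δ)·tanh(β·IC(c))`` with Δ = IC(a)+IC(b)−2·IC(c)."""
    c = taxonomy.lca(a, b)
    ic_c = ic(taxonomy, c, ic_method)
    delta = ic(taxonomy, a, ic_method) + ic(taxonomy, b, ic_method) - 2.0 * ic_c
    return 1.0 - math.exp(-alpha * delta) * math.tanh(beta * ic_c)


def cs_simplified(taxonomy: Taxonomy, ic_method: ICMethod | str, a: str, b: str) -> float:
    """Deepest-level simplification ``(IC(l) − IC(c)) / IC(l)``."""
    ic_l = _max_ic(taxonomy, ic_method)
    if ic_l == 0.0:
        raise DomainError(
            "cs_simplified undefined on a taxonomy whose maximum IC is 0 "
            "(single-node taxonomy under ontology IC)"
        )
    c = taxonomy.lca(a, b)
    return (ic_l - ic(taxonomy, c, ic_method)) / ic_l


def _max_ic(taxonomy: Taxonomy, ic_method: ICMethod | str) -> float:
    ic_method = ICMethod.parse(ic_method)
    cache = taxonomy._memo.setdefault("max_ic", {})
    if ic_method not in cache:
        cache[ic_method] = max(ic(taxonomy, code, ic_method) for code in taxonomy.nodes)
    return cache[ic_method]


def concept_distance(
    taxonomy: Taxonomy,
    ic_method: ICMethod | str,
    cs: CSMethod | str,
    a: str,
    b: str,
) -> float:
    """Dispatch to the selected CS formula, memoized per unordered pair.

    All four measures are symmetric, so the cache is keyed on the sorted
    pair; this halves the work of the all-pairs prototype-score step.
    """
    cs = CSMethod.parse(cs)
    ic_method = ICMethod.parse(ic_method)
    key = ("cs", ic_method, cs)
    cache = taxonomy._memo.setdefault(key, {})
    pair = (a, b) if a <= b else (b, a)
    if pair not in cache:
        if cs.method_id == "binary":
            value = cs_binary(a, b)
        elif cs.method_id == "wu":
            value = cs_wu(taxonomy, ic_method, a, b)
        elif cs.method_id == "li":
            value = cs_li(taxonomy, ic_method, a, b, cs.alpha, cs.beta)
        else:
            value = cs_simplified(taxonomy, ic_method, a, b)
        cache[pair] = value
    return cache[pair]
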