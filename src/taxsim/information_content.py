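"""Information content (IC) of taxonomy nodes.

Two information-theoretic IC measures are supported:

* ``path`` — the node's 1-based level, i.e. the count of levels on the path
  from the node to the root inclusive of both ends. The virtual root has
  IC 1, a chapter 2, and a full ICD-10 expansion code 5.
* ``ontology`` — the structural-intrinsic measure of Sánchez et al.::

      IC(a) = -log( (|leaves(a)| / |subsumers(a)| + 1) / (|leaves(root)| + 1) )

  which is 0 at the root and strictly increases along every root-to-leaf
  path. The logarithm is natural by default; the base cancels inside
  IC-ratio distances and only rescales exponent-based ones.

Values are memoized per taxonomy because the ontology measure requires leaf
counts over every hyponym subtree.
"""

from __future__ import annotations

import math
from enum import Enum

from .errors import ConfigurationError
from .taxonomy import Taxonomy

__all__ = ["ICMethod", "ic", "ic_path", "ic_ontology"]


class ICMethod(str, Enum):
    """Choice of information-content measure (the IC slot of a ⟨IC,CS,SS⟩ triple)."""

    PATH = "path"
    ONTOLOGY = "ontology"

    @classmethod
    def parse(cls, value: "ICMethod | str") -> "ICMethod":
        if isinstance(value, cls):
            return value
        try:
            return cls(value)
        except ValueError:
            raise ConfigurationError(
                f"unknown IC method {value!r}; expected one of {[m.value for m in cls]}"
            ) from None


def ic_path(taxonomy: Taxonomy, code: str) -> float:
    """Path-based IC: the number of levels from ``code`` to the root, inclusive."""
    return float(taxonomy.level_of(code))


def ic_ontology(taxonomy: Taxonomy, code: str, *, base: float = math.e) -> float:
    """Leaf/subsumer-based IC; 0 at the root, increasing with specificity."""
    ratio = taxonomy.leaves_count(code) / taxonomy.subsumers_count(code)
    value = -math.log((ratio + 1.0) / (taxonomy.leaves_count(taxonomy.root) + 1.0))
    if base != math.e:
        value /= math.log(base)
    return value


def ic(taxonomy: Taxonomy, code: str, method: ICMethod | str) -> float:
    """Dispatch to the selected IC measure, memoized per taxonomy."""
    method = ICMethod.parse(method)
    cache = taxonomy._memo.setdefault(("ic", method), {})
    if code not in cache:
        fn = ic_path if method is ICMethod.PATH else ic_ontology
        cache[code] = fn(taxonomy, code)
    return cache[code]
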