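"""Rooted, level-labelled concept taxonomies and their structural queries.

A taxonomy is a single-rooted tree of concept codes (plain strings, compared
case-sensitively). Levels are 1-based from the root, so a chapter of an
ICD-10-style hierarchy sits at level 2 and a full expansion code at level 5.
All distance formulas reduce to four structural queries answered here: least
common ancestor, depth (level), leaf counts of the hyponym subtree, and
subsumer (ancestor-or-self) counts.
"""

from __future__ import annotations

import re
from collections import deque
from typing import Iterable, Iterator, Mapping

from .errors import CodeParseError, StructuralError, UnknownCodeError

__all__ = [
    "ROOT_CODE",
    "Taxonomy",
    "load_edge_list",
    "save_edge_list",
    "derive_icd10_hierarchy",
]

#: Name of the virtual root node synthesized for derived hierarchies.
ROOT_CODE = "ROOT"

_CODE_RE = re.compile(r"\S+")
_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9A-Za-z]{1,3})?$")


class Taxonomy:
    """A validated single-rooted tree over concept codes.

    Parameters
    ----------
    parent_of
        Mapping from each non-root code to its parent code.
    root
        The root code; must not appear as a key of ``parent_of``.

    Raises
    ------
    StructuralError
        If the mapping does not describe a single-rooted acyclic tree whose
        every parent is itself a node.
    """

    def __init__(self, parent_of: Mapping[str, str], root: str):
        for code in list(parent_of) + [root]:
            if not _CODE_RE.fullmatch(code):
                raise StructuralError(f"invalid concept code {code!r}: must be a non-empty token")
        if root in parent_of:
            raise StructuralError(f"root {root!r} must not have a parent")
        self.root = root
        self.parent_of: dict[str, str] = dict(parent_of)
        self._children: dict[str, list[str]] = {root: []}
        for child, parent in self.parent_of.items():
            self._children.setdefault(child, [])
            self._children.setdefault(parent, []).append(child)
        orphans = [p for p in set(self.parent_of.values()) if p != root and p not in self.parent_of]
        if orphans:
            raise StructuralError(
                f"parent {sorted(orphans)[0]!r} is not itself a node (orphan parent / multiple roots)"
            )
        # BFS from the root assigns levels and proves acyclicity/connectedness.
        self._level: dict[str, int] = {root: 1}
        queue = deque([root])
        while queue:
            node = queue.popleft()
            for child in self._children[node]:
                self._level[child] = self._level[node] + 1
                queue.append(child)
        if len(self._level) != len(self._children):
            unreached = sorted(set(self._children) - set(self._level))
            raise StructuralError(f"cycle or disconnected subtree involving node {unreached[0]!r}")
        for children in self._children.values():
            children.sort()
        self._leaves_count: dict[str, int] = {}
        self._memo: dict[object, dict] = {}  # caches for IC / pairwise-distance consumers

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self._children)

    def __contains__(self, code: str) -> bool:
        return code in self._children

    def __len__(self) -> int:
        return len(self._children)

    def _require(self, code: str) -> None:
        if code not in self._children:
            raise UnknownCodeError(f"unknown concept code {code!r}")

    def level_of(self, code: str) -> int:
        """1-based depth of ``code`` (root has level 1)."""
        self._require(code)
        return self._level[code]

    @property
    def max_level(self) -> int:
        """Total number of levels L (depth of the deepest node)."""
        return max(self._level.values())

    def children_of(self, code: str) -> tuple[str, ...]:
        self._require(code)
        return tuple(self._children[code])

    def is_leaf(self, code: str) -> bool:
        self._require(code)
        return not self._children[code]

    def ancestors(self, code: str) -> Iterator[str]:
        """Yield ``code`` and then each ancestor up to and including the root."""
        self._require(code)
        node = code
        while True:
            yield node
            if node == self.root:
                return
            node = self.parent_of[node]

    def iter_edges(self) -> Iterator[tuple[str, str]]:
        """(child, parent) pairs in deterministic (sorted-child) order."""
        for child in sorted(self.parent_of):
            yield child, self.parent_of[child]

    # -- structural queries ------------------------------------------------

    def lca(self, a: str, b: str) -> str:
        """Deepest node that is an ancestor-or-self of both ``a`` and ``b``."""
        self._require(a)
        self._require(b)
        seen = set(self.ancestors(a))
        for node in self.ancestors(b):
            if node in seen:
                return node
        raise StructuralError("no common ancestor; tree invariant violated")  # pragma: no cover

    def leaves_count(self, code: str) -> int:
        """Number of leaves in the subtree rooted at ``code`` (a leaf counts itself)."""
        self._require(code)
        if code not in self._leaves_count:
            # iterative post-order; taxonomies can be a few levels deep but wide
            stack = [(code, False)]
            while stack:
                node, expanded = stack.pop()
                if node in self._leaves_count:
                    continue
                kids = self._children[node]
                if not kids:
                    self._leaves_count[node] = 1
                elif expanded:
                    self._leaves_count[node] = sum(self._leaves_count[k] for k in kids)
                else:
                    stack.append((node, True))
                    stack.extend((k, False) for k in kids)
        return self._leaves_count[code]

    def subsumers_count(self, code: str) -> int:
        """Number of ancestors of ``code`` including itself (= its level in a tree)."""
        return self.level_of(code)


def load_edge_list(path) -> Taxonomy:
    """Read a two-column (child, parent) delimited text file into a Taxonomy.

    Tab- or comma-delimited; lines starting with ``#`` are ignored. The root
    may be declared explicitly by a row whose parent field is ``-``; otherwise
    the unique code appearing only on the parent side is taken as the root.
    """
    parent_of: dict[str, str] = {}
    roots: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split(",")
            if len(fields) != 2:
                raise StructuralError(f"{path}:{lineno}: expected two columns, got {len(fields)}")
            child, parent = (f.strip() for f in fields)
            if parent == "-":
                roots.append(child)
                continue
            if child in parent_of:
                raise StructuralError(f"{path}:{lineno}: duplicate child row for {child!r}")
            parent_of[child] = parent
    if not roots:
        children = set(parent_of)
        roots = sorted(set(parent_of.values()) - children)
    if len(roots) != 1:
        raise StructuralError(f"{path}: expected exactly one root, found {sorted(roots)!r}")
    if roots[0] in parent_of:
        raise StructuralError(f"{path}: declared root {roots[0]!r} also has a parent row")
    return Taxonomy(parent_of, roots[0])


def save_edge_list(taxonomy: Taxonomy, path) -> None:
    """Write a Taxonomy as a tab-delimited (child, parent) file with a root row."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{taxonomy.root}\t-\n")
        for child, parent in taxonomy.iter_edges():
            fh.write(f"{child}\t{parent}\n")


def derive_icd10_hierarchy(codes: Iterable[str]) -> Taxonomy:
    """Reconstruct a 5-level hierarchy from the lexical structure of ICD-10-style codes.

    Levels are: virtual root (1) → chapter, the first letter (2) → category,
    the first three characters (3) → subcategory, the first five characters
    such as ``M06.9`` (4) → expansion code, the full string (5). Codes lacking
    deeper characters attach at their deepest derivable level, so a bare
    ``M06`` is a level-3 node.
    """
    parent_of: dict[str, str] = {}

    def link(child: str, parent: str) -> None:
        prev = parent_of.setdefault(child, parent)
        if prev != parent:  # pragma: no cover - unreachable for prefix-derived chains
            raise StructuralError(f"conflicting parents {prev!r}/{parent!r} for {child!r}")

    for code in codes:
        if not _ICD10_RE.match(code):
            raise CodeParseError(
                f"code {code!r} does not match the ICD-10 lexical pattern "
                "(letter + 2 digits, optionally '.' + up to 3 characters)"
            )
        chain = [ROOT_CODE, code[0], code[:3]]
        if len(code) > 3:
            chain.append(code[:5])
        if len(code) > 5:
            chain.append(code)
        for parent, child in zip(chain, chain[1:]):
            link(child, parent)
    return Taxonomy(parent_of, ROOT_CODE)
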