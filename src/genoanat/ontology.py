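"""Hierarchical anatomical ontology: terms, trees, and level-wise ancestry.

The developing-brain reference ontology is a rooted tree of named, colored
structures. The root (level 0) is the undivided neural plate; each term at
level ``l`` subdivides into child terms at level ``l + 1``, down to at most
level 12. Every voxel of the annotation volume carries one term id; analyses
at a coarser granularity replace that id by its ancestor at a fixed level
("up-propagation").

The JSON interchange format is a flat array of objects
``{id, acronym, name, level, parent_id, color_hex}``, mirroring the
structure-graph payloads served by common atlas APIs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .exceptions import DomainError, IntegrityError, LookupError_

__all__ = ["OntologyTerm", "OntologyTree", "ancestor_at_level"]


@dataclass(frozen=True)
class OntologyTerm:
    """One anatomical structure.

    Parameters
    ----------
    id : int
        Unique integer identifier (strictly positive; 0 is reserved for
        unannotated/background voxels).
    acronym : str
        Short display string, e.g. ``"p1"`` or ``"PHy"``.
    name : str
        Full structure name.
    level : int
        Depth in the hierarchy; the root has level 0.
    parent_id : int | None
        Parent term id; ``None`` only for the root.
    color : str
        RGB hex string ``"#rrggbb"`` used for plotting.
    """

    id: int
    acronym: str
    name: str
    level: int
    parent_id: int | None
    color: str = "#808080"

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise IntegrityError(f"term id must be positive, got {self.id}")
        if self.level < 0:
            raise IntegrityError(f"term level must be >= 0, got {self.level}")
        if (self.parent_id is None) != (self.level == 0):
            raise IntegrityError(
                f"term {self.id}: parent_id is None iff level == 0 "
                f"(level={self.level}, parent_id={self.parent_id})"
            )


class OntologyTree:
    """A rooted tree of :class:`OntologyTerm` with O(1) id lookup.

    Invariants checked at construction: exactly one root, unique ids, every
    ``parent_id`` resolves, and every non-root term's level is its parent's
    level plus one (which also rules out cycles).
    """

    def __init__(self, terms: Iterable[OntologyTerm]):
        self._terms: dict[int, OntologyTerm] = {}
        for t in terms:
            if t.id in self._terms:
                raise IntegrityError(f"duplicate term id {t.id}")
            self._terms[t.id] = t
        roots = [t for t in self._terms.values() if t.parent_id is None]
        if len(roots) != 1:
            raise IntegrityError(f"tree must have exactly one root, found {len(roots)}")
        self.root_id: int = roots[0].id
        self._children: dict[int, list[int]] = {tid: [] for tid in self._terms}
        for t in self._terms.values():
            if t.parent_id is None:
                continue
            parent = self._terms.get(t.parent_id)
            if parent is None:
                raise IntegrityError(
                    f"term {t.id}: parent_id {t.parent_id} not in tree"
                )
            if t.level != parent.level + 1:
                raise IntegrityError(
                    f"term {t.id}: level {t.level} != parent level {parent.level} + 1"
                )
            self._children[parent.id].append(t.id)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._terms)

    def __contains__(self, term_id: int) -> bool:
        return term_id in self._terms

    def __iter__(self) -> Iterator[OntologyTerm]:
        return iter(self._terms.values())

    def __getitem__(self, term_id: int) -> OntologyTerm:
        try:
            return self._terms[term_id]
        except KeyError:
            raise LookupError_(f"unknown ontology term id {term_id}") from None

    # -- queries ------------------------------------------------------------
    def children(self, term_id: int) -> list[int]:
        self[term_id]
        return list(self._children[term_id])

    def terms_at_level(self, level: int) -> list[OntologyTerm]:
        return [t for t in self._terms.values() if t.level == level]

    @property
    def max_level(self) -> int:
        return max(t.level for t in self._terms.values())

    def path_to_root(self, term_id: int) -> list[int]:
        """Ids from ``term_id`` up to and including the root."""
        path = [term_id]
        t = self[term_id]
        while t.parent_id is not None:
            path.append(t.parent_id)
            t = self[t.parent_id]
        return path

    # -- JSON interchange ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        records = [
            {
                "id": t.id,
                "acronym": t.acronym,
                "name": t.name,
                "level": t.level,
                "parent_id": t.parent_id,
                "color_hex": t.color,
            }
            for t in sorted(self._terms.values(), key=lambda t: t.id)
        ]
        Path(path).write_text(json.dumps(records, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "OntologyTree":
        records = json.loads(Path(path).read_text())
        terms = [
            OntologyTerm(
                id=int(r["id"]),
                acronym=str(r["acronym"]),
                name=str(r["name"]),
                level=int(r["level"]),
                parent_id=None if r["parent_id"] is None else int(r["parent_id"]),
                color=str(r.get("color_hex", "#808080")),
            )
            for r in records
        ]
        return cls(terms)


def ancestor_at_level(tree: OntologyTree, term_id: int, level: int) -> int:
    """Return the id of the unique ancestor of ``term_id`` at ``level``.

    The term itself is returned when it already sits at the requested level.
    Because every term's level is its parent's level + 1, the ancestor at any
    level between 0 and the term's own level exists and is unique.

    Raises
    ------
    LookupError_
        If ``term_id`` is not in the tree.
    DomainError
        If ``level`` is negative or exceeds the term's level (annotations can
        be propagated *up* the hierarchy only).
    """
    term = tree[term_id]
    if level < 0 or level > term.level:
        raise DomainError(
            f"cannot propagate term {term_id} (level {term.level}) to level {level}"
        )
    while term.level > level:
        term = tree[term.parent_id]  # type: ignore[arg-type]  # non-root here
    return term.id
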