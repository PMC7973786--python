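"""Anatomical ontology: a rooted tree of brain structures.

The ontology (AO) is the JSON text file that defines the anatomical
hierarchy: every brain structure is a *node* with an integer id, a name,
an acronym and a parent; a *leaf* has no children, an *inner* node has at
least one, and the single *root* has no parent.  Two JSON dialects are
read: the Allen Institute dialect (a top-level ``"msg"`` list holding one
root with nested ``"children"``) and a plain nested-node dialect used for
fixtures and round-tripping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

from .errors import ConfigurationError, ConsistencyError, OntologyIntegrityError, OntologyLookupError

__all__ = [
    "OntologyNode",
    "AnnotationOntology",
    "NodeClassification",
    "load_ontology",
    "save_ontology",
    "classify_nodes",
    "select_parenchyma",
]


@dataclass
class OntologyNode:
    """One brain structure in the hierarchy.

    ``size_nl`` is the voxel count of the structure in the annotation
    volume (1 voxel = 1 nL at 100 µm isotropic resolution); it is absent
    until appended by preprocessing.
    """

    id: int
    name: str
    acronym: str
    parent_id: int | None
    children_ids: list[int] = field(default_factory=list)
    color_hex: str | None = None
    size_nl: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children_ids

    def copy(self) -> "OntologyNode":
        return replace(self, children_ids=list(self.children_ids))


class AnnotationOntology:
    """A validated rooted tree of :class:`OntologyNode`.

    Invariants (enforced by :meth:`validate`): ids are unique, exactly one
    node has no parent (the root), every node is reachable from the root,
    and parent/child links are mutually consistent.
    """

    def __init__(self, nodes: dict[int, OntologyNode], root_id: int, validate: bool = True):
        self.nodes = nodes
        self.root_id = root_id
        if validate:
            self.validate()

    # -- construction ----------------------------------------------------
    @classmethod
    def from_nodes(cls, nodes: list[OntologyNode]) -> "AnnotationOntology":
        mapping: dict[int, OntologyNode] = {}
        for n in nodes:
            if n.id in mapping:
                raise OntologyIntegrityError(f"duplicate node id {n.id}")
            mapping[n.id] = n
        roots = [n.id for n in nodes if n.parent_id is None]
        if len(roots) != 1:
            raise OntologyIntegrityError(f"expected exactly one root, found {sorted(roots)}")
        return cls(mapping, roots[0])

    def validate(self) -> None:
        nodes = self.nodes
        if self.root_id not in nodes:
            raise OntologyIntegrityError(f"root id {self.root_id} not among nodes")
        roots = [i for i, n in nodes.items() if n.parent_id is None]
        if roots != [self.root_id] and set(roots) != {self.root_id}:
            raise OntologyIntegrityError(f"multiple or misplaced roots: {sorted(roots)}")
        for i, n in nodes.items():
            if n.id != i:
                raise OntologyIntegrityError(f"node keyed {i} carries id {n.id}")
            if n.id < 1:
                raise OntologyIntegrityError(f"node id must be >= 1, got {n.id}")
            if len(set(n.children_ids)) != len(n.children_ids) or n.id in n.children_ids:
                raise OntologyIntegrityError(f"invalid children list of node {n.id}")
            for c in n.children_ids:
                if c not in nodes:
                    raise OntologyIntegrityError(f"node {n.id} lists missing child {c}")
                if nodes[c].parent_id != n.id:
                    raise OntologyIntegrityError(
                        f"child {c} of node {n.id} declares parent {nodes[c].parent_id}"
                    )
            if n.parent_id is not None:
                if n.parent_id not in nodes:
                    raise OntologyIntegrityError(f"node {n.id} references missing parent {n.parent_id}")
                if n.id not in nodes[n.parent_id].children_ids:
                    raise OntologyIntegrityError(f"node {n.id} absent from children of {n.parent_id}")
        # reachability / acyclicity
        seen: set[int] = set()
        stack = [self.root_id]
        while stack:
            i = stack.pop()
            if i in seen:
                raise OntologyIntegrityError(f"cycle through node {i}")
            seen.add(i)
            stack.extend(self.nodes[i].children_ids)
        orphans = set(nodes) - seen
        if orphans:
            raise OntologyIntegrityError(f"orphan nodes unreachable from root: {sorted(orphans)}")

    # -- queries ---------------------------------------------------------
    def node(self, node_id: int) -> OntologyNode:
        try:
            return self.nodes[node_id]
        except KeyError:
            raise OntologyLookupError(f"unknown node id {node_id}") from None

    def __contains__(self, node_id: int) -> bool:
        return node_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def __eq__(self, other) -> bool:
        if not isinstance(other, AnnotationOntology):
            return NotImplemented
        return self.root_id == other.root_id and self.nodes == other.nodes

    def by_acronym(self, acronym: str) -> OntologyNode:
        for n in self.nodes.values():
            if n.acronym == acronym:
                return n
        raise OntologyLookupError(f"no node with acronym {acronym!r}")

    def resolve(self, ref: int | str) -> int:
        """Resolve a node reference (integer id or acronym string) to an id."""
        if isinstance(ref, int):
            return self.node(ref).id
        if isinstance(ref, str) and ref.lstrip("-").isdigit():
            return self.node(int(ref)).id
        return self.by_acronym(ref).id

    def leaf_ids(self) -> list[int]:
        return sorted(i for i, n in self.nodes.items() if n.is_leaf)

    def inner_ids(self) -> list[int]:
        return sorted(i for i, n in self.nodes.items() if not n.is_leaf)

    def descendants(self, node_id: int) -> set[int]:
        """All nodes strictly below ``node_id``."""
        self.node(node_id)
        out: set[int] = set()
        stack = list(self.nodes[node_id].children_ids)
        while stack:
            i = stack.pop()
            out.add(i)
            stack.extend(self.nodes[i].children_ids)
        return out

    def ancestors(self, node_id: int) -> list[int]:
        """Ancestors ordered child→root (``node_id`` itself excluded)."""
        n = self.node(node_id)
        out: list[int] = []
        while n.parent_id is not None:
            out.append(n.parent_id)
            n = self.nodes[n.parent_id]
        return out

    def leaves_under(self, node_id: int) -> set[int]:
        """Leaf nodes in the subtree of ``node_id`` (a leaf maps to itself)."""
        n = self.node(node_id)
        if n.is_leaf:
            return {node_id}
        return {i for i in self.descendants(node_id) if self.nodes[i].is_leaf}

    def preorder(self, start: int | None = None) -> list[int]:
        """Depth-first pre-order ids, following the stored children order."""
        start = self.root_id if start is None else start
        out: list[int] = []
        stack = [start]
        while stack:
            i = stack.pop()
            out.append(i)
            stack.extend(reversed(self.nodes[i].children_ids))
        return out

    def copy(self) -> "AnnotationOntology":
        return AnnotationOntology(
            {i: n.copy() for i, n in self.nodes.items()}, self.root_id, validate=False
        )


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def _node_from_dict(d: dict, parent_id: int | None, out: list[OntologyNode], aibs: bool) -> None:
    if aibs:
        node = OntologyNode(
            id=int(d["id"]),
            name=str(d.get("name", "")),
            acronym=str(d.get("acronym", "")),
            parent_id=parent_id,
            children_ids=[int(c["id"]) for c in d.get("children") or []],
            color_hex=d.get("color_hex_triplet"),
            size_nl=d.get("size_nl"),
        )
    else:
        node = OntologyNode(
            id=int(d["id"]),
            name=str(d.get("name", "")),
            acronym=str(d.get("acronym", "")),
            parent_id=parent_id,
            children_ids=[int(c["id"]) for c in d.get("children") or []],
            color_hex=d.get("color_hex"),
            size_nl=d.get("size_nl"),
        )
    out.append(node)
    for c in d.get("children") or []:
        _node_from_dict(c, node.id, out, aibs)


def load_ontology(json_text: str) -> AnnotationOntology:
    """Parse an ontology JSON text in either supported dialect.

    Dialect detection: a top-level object with a ``"msg"`` list is the
    Allen Institute form; otherwise the document itself is taken to be a
    nested root-node object.  Children order is preserved as in the file.
    """
    doc = json.loads(json_text)
    nodes: list[OntologyNode] = []
    if isinstance(doc, dict) and "msg" in doc:
        roots = doc["msg"]
        if not isinstance(roots, list) or len(roots) != 1:
            raise OntologyIntegrityError("AIBS 'msg' must contain exactly one root node")
        _node_from_dict(roots[0], None, nodes, aibs=True)
    elif isinstance(doc, dict) and "id" in doc:
        _node_from_dict(doc, None, nodes, aibs=False)
    else:
        raise OntologyIntegrityError("unrecognized ontology JSON dialect")
    return AnnotationOntology.from_nodes(nodes)


def _node_to_dict(onto: AnnotationOntology, node_id: int) -> dict:
    n = onto.nodes[node_id]
    d: dict = {"id": n.id, "name": n.name, "acronym": n.acronym}
    if n.color_hex is not None:
        d["color_hex"] = n.color_hex
    if n.size_nl is not None:
        d["size_nl"] = int(n.size_nl)
    d["children"] = [_node_to_dict(onto, c) for c in n.children_ids]
    return d


def save_ontology(onto: AnnotationOntology) -> str:
    """Serialize to the plain nested dialect; ``load_ontology`` inverts it."""
    return json.dumps(_node_to_dict(onto, onto.root_id), indent=1)


# ---------------------------------------------------------------------------
# classification against an annotation volume
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeClassification:
    """Partition of non-root nodes by AO↔AV consistency.

    A *destructive* leaf has no voxels in the annotation volume; a
    *destructive* inner node carries voxels of its own.  Either breaks the
    one-to-one correspondence between ontology leaves and volume labels
    that combining/dividing relies on.
    """

    destructive_leaves: frozenset[int]
    destructive_inners: frozenset[int]
    consistent_leaves: frozenset[int]
    consistent_inners: frozenset[int]


def classify_nodes(onto: AnnotationOntology, sizes: dict[int, int]) -> NodeClassification:
    """Classify every node by leaf/inner status and voxel backing.

    ``sizes`` maps volume labels to voxel counts (ids absent from the map
    have zero voxels).  Labels not present in the ontology are a
    consistency error.
    """
    unknown = sorted(i for i, c in sizes.items() if c > 0 and i not in onto.nodes)
    if unknown:
        raise ConsistencyError(f"volume labels absent from ontology: {unknown}")
    dl, di, cl, ci = set(), set(), set(), set()
    for i, n in onto.nodes.items():
        own = sizes.get(i, 0)
        if n.is_leaf:
            (dl if own == 0 else cl).add(i)
        else:
            (di if own > 0 else ci).add(i)
    return NodeClassification(frozenset(dl), frozenset(di), frozenset(cl), frozenset(ci))


def select_parenchyma(
    onto: AnnotationOntology,
    grey_acronym: str = "grey",
    fiber_acronym: str = "fiber tracts",
    ventricle_acronym: str = "VS",
) -> set[int]:
    """Ids of the grey-matter branch (brain parenchyma).

    Functional-connectivity analysis excludes fiber tracts and the
    ventricular systems; this returns the grey branch node and all of its
    descendants.  On a double-sided atlas the branch acronyms carry
    ``_L``/``_R`` suffixes; both sides are returned.  All three configured
    branches must exist (on at least one side) or a
    :class:`ConfigurationError` is raised.
    """
    out: set[int] = set()
    for base, collect in ((grey_acronym, True), (fiber_acronym, False), (ventricle_acronym, False)):
        matches = [
            n.id
            for n in onto.nodes.values()
            if n.acronym in (base, base + "_L", base + "_R")
        ]
        if not matches:
            raise ConfigurationError(f"branch acronym {base!r} not found in ontology")
        if collect:
            for m in matches:
                out.add(m)
                out |= onto.descendants(m)
    return out
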