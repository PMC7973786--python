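"""Preprocessing an ontology + annotation volume into a consistent atlas base.

The original Allen resources are mutually inconsistent: some ontology
leaves have no voxels in the annotation volume, and some inner nodes
carry voxels of their own.  Both kinds of *destructive* node break the
leaf↔label bijection that combining and dividing rely on.  Preprocessing
removes them in four steps:

1. prune voxel-less leaves (iterated to a fixpoint, so an inner node
   stranded childless without voxels is removed too);
2. split each voxel-carrying inner node X into the inner node X plus a
   new leaf ``X_peri`` that takes over X's own voxels;
3. relabel the volume accordingly;
4. append voxel counts (= sizes in nL at 100 µm) to every node.

The resulting (ontology, volume) pair — the atlas *base* — satisfies:
every leaf has voxels, no inner node does, and leaf sizes equal voxel
counts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AllocationError, ConsistencyError, OntologyIntegrityError
from .ontology import AnnotationOntology, OntologyNode, classify_nodes
from .volume import LabeledVolume, label_sizes, remap_labels

__all__ = [
    "FAA",
    "IdAllocator",
    "prune_voxelless_leaves",
    "split_destructive_inners",
    "append_sizes",
    "build_faa_base",
    "validate_faa",
]


@dataclass
class FAA:
    """A flexible annotation atlas: an ontology and a volume that agree."""

    ontology: AnnotationOntology
    volume: LabeledVolume
    provenance: list[str] = field(default_factory=list)

    def log(self, message: str) -> None:
        self.provenance.append(message)


class IdAllocator:
    """Fresh node ids: start at the next power of ten above the current
    maximum id and count up.  Keeps new ids visually distinct from
    original ones and collision-free."""

    def __init__(self, existing_ids):
        existing = set(int(i) for i in existing_ids)
        hi = max(existing) if existing else 0
        start = 10
        while start <= hi:
            start *= 10
        self._next = start
        self._taken = existing

    @property
    def next_preview(self) -> int:
        return self._next

    def allocate(self) -> int:
        nid = self._next
        if nid in self._taken:
            raise AllocationError(f"fresh id {nid} collides with an existing node")
        self._taken.add(nid)
        self._next += 1
        return nid


def prune_voxelless_leaves(
    onto: AnnotationOntology, sizes: dict[int, int]
) -> tuple[AnnotationOntology, list[int]]:
    """Remove every leaf without voxels, iterating to a fixpoint.

    A single pass can strand an inner node childless (all children
    removed); if such a node has no voxels of its own it is itself a
    voxel-less leaf and is removed on the next pass.  Returns the pruned
    ontology and the removed ids (ascending).
    """
    out = onto.copy()
    removed: list[int] = []
    while True:
        doomed = [
            i for i, n in out.nodes.items()
            if n.is_leaf and sizes.get(i, 0) == 0
        ]
        if not doomed:
            break
        if out.root_id in doomed:
            raise OntologyIntegrityError(
                "pruning would remove the root: no leaf in the ontology has voxels"
            )
        for i in doomed:
            parent = out.nodes[out.nodes[i].parent_id]
            parent.children_ids.remove(i)
            del out.nodes[i]
            removed.append(i)
    out.validate()
    return out, sorted(removed)


def split_destructive_inners(
    onto: AnnotationOntology, sizes: dict[int, int], allocator: IdAllocator
) -> tuple[AnnotationOntology, dict[int, int]]:
    """Give each voxel-carrying inner node a new leaf child for its voxels.

    Node X keeps its id and children and gains a leaf named
    "<name>, peripheral" / acronym "<acronym>_peri" with a fresh id; the
    returned relabel mapping sends X's id to the new leaf id so the
    volume can be updated.  A destructive inner reduced to a leaf by
    pruning stays a plain leaf (its voxels are already legitimate).
    """
    out = onto.copy()
    mapping: dict[int, int] = {}
    for i in sorted(out.nodes):
        n = out.nodes[i]
        if n.is_leaf or sizes.get(i, 0) == 0:
            continue
        new_id = allocator.allocate()
        leaf = OntologyNode(
            id=new_id,
            name=f"{n.name}, peripheral",
            acronym=f"{n.acronym}_peri",
            parent_id=n.id,
            children_ids=[],
            color_hex=n.color_hex,
        )
        out.nodes[new_id] = leaf
        n.children_ids.append(new_id)
        mapping[i] = new_id
    out.validate()
    return out, mapping


def append_sizes(onto: AnnotationOntology, sizes: dict[int, int]) -> None:
    """Set ``size_nl`` in place: leaves from voxel counts, inner nodes as
    the sum over their leaves (post-order accumulation)."""
    for i in reversed(onto.preorder()):
        n = onto.nodes[i]
        if n.is_leaf:
            n.size_nl = int(sizes.get(i, 0))
        else:
            n.size_nl = int(sum(onto.nodes[c].size_nl or 0 for c in n.children_ids))


def build_faa_base(
    onto: AnnotationOntology,
    vol: LabeledVolume,
    on_unknown_label: str = "error",
) -> FAA:
    """Run the full four-step preprocessing and return a consistent atlas.

    ``on_unknown_label`` controls volume labels absent from the ontology:
    ``"error"`` (default) raises; ``"quarantine"`` collects them into a
    synthetic "unassigned" leaf under the root so the inconsistency is
    visible rather than silent.
    """
    provenance: list[str] = []
    sizes = label_sizes(vol)
    unknown = sorted(i for i in sizes if i not in onto.nodes)
    if unknown:
        if on_unknown_label == "quarantine":
            onto = onto.copy()
            allocator = IdAllocator(set(onto.nodes) | set(sizes))
            qid = allocator.allocate()
            onto.nodes[qid] = OntologyNode(
                id=qid, name="unassigned voxels", acronym="unassigned",
                parent_id=onto.root_id, children_ids=[],
            )
            onto.nodes[onto.root_id].children_ids.append(qid)
            vol = remap_labels(vol, {u: qid for u in unknown})
            sizes = label_sizes(vol)
            provenance.append(f"quarantined unknown labels {unknown} into node {qid} 'unassigned'")
        elif on_unknown_label == "error":
            raise ConsistencyError(f"volume labels absent from ontology: {unknown}")
        else:
            raise ValueError(f"on_unknown_label must be 'error' or 'quarantine', got {on_unknown_label!r}")

    pruned, removed = prune_voxelless_leaves(onto, sizes)
    provenance.append(f"pruned {len(removed)} voxel-less nodes: {removed}")

    allocator = IdAllocator(set(onto.nodes) | set(sizes))
    split, mapping = split_destructive_inners(pruned, sizes, allocator)
    provenance.append(
        "split {} voxel-carrying inner nodes into inner + peripheral leaf: {}".format(
            len(mapping), {k: v for k, v in sorted(mapping.items())}
        )
    )

    new_vol = remap_labels(vol, mapping) if mapping else vol
    new_sizes = label_sizes(new_vol)
    append_sizes(split, new_sizes)
    provenance.append(
        f"atlas base: {len(split)} nodes "
        f"({len(split.inner_ids())} inner, {len(split.leaf_ids())} leaf)"
    )
    faa = FAA(split, new_vol, provenance)
    validate_faa(faa)
    return faa


def validate_faa(faa: FAA) -> None:
    """Check the atlas invariants: nonzero volume labels and voxel-backed
    ontology leaves are in bijection, no inner id occurs in the volume,
    and recorded sizes match voxel counts."""
    sizes = label_sizes(faa.volume)
    leaf_ids = set(faa.ontology.leaf_ids())
    labels = set(sizes)
    if not labels <= leaf_ids:
        raise ConsistencyError(
            f"volume labels that are not ontology leaves: {sorted(labels - leaf_ids)}"
        )
    sized_leaves = {i for i in leaf_ids if (faa.ontology.nodes[i].size_nl or 0) > 0}
    if sized_leaves != labels:
        raise ConsistencyError(
            "leaf/label mismatch: leaves with size but no voxels "
            f"{sorted(sized_leaves - labels)}, labels missing sizes {sorted(labels - sized_leaves)}"
        )
    for i in leaf_ids:
        rec = faa.ontology.nodes[i].size_nl
        if rec is not None and rec != sizes.get(i, 0):
            raise ConsistencyError(
                f"leaf {i}: recorded size {rec} != voxel count {sizes.get(i, 0)}"
            )
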