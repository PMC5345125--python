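"""The parentEventID sampling-event hierarchy.

A cruise contains station visits, a station visit contains gear
deployments, a grab sample may be split into subsamples: the hierarchy keeps
each level's metadata (coordinates, dates, depths) at the level where it was
actually determined, instead of repeating it on every leaf.  This module
builds the tree, resolves inherited metadata, names events hierarchically
(``station5:sample1:subsample2``) and labels events by depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import (CycleError, DanglingParentError, DepthExceedsLabelsError,
                     DuplicateEventIDError, SeparatorInLabelError,
                     UnknownEventError)
from .model import EventRecord, get_field

__all__ = ["EventTree", "build_tree", "resolve_inherited",
           "resolve_inherited_coordinates", "hierarchical_id",
           "annotate_levels", "DEFAULT_INHERIT_FIELDS"]

#: Fields flattening inherits by default.  Depth fields deliberately do NOT
#: inherit: a reading's depth must never be replaced by the cast's range.
DEFAULT_INHERIT_FIELDS = ("eventDate", "decimalLatitude",
                          "decimalLongitude", "footprintWKT")


@dataclass
class EventTree:
    """Events indexed by ID with parent/child links; sibling order is input
    order (no implicit sorting)."""

    nodes: dict[str, EventRecord] = field(default_factory=dict)
    children: dict[str, list[str]] = field(default_factory=dict)
    roots: list[str] = field(default_factory=list)

    def depth_of(self, event_id: str) -> int:
        """0-based depth (roots are depth 0)."""
        record = self._get(event_id)
        depth = 0
        while record.parentEventID in self.nodes:
            record = self.nodes[record.parentEventID]
            depth += 1
        return depth

    def path_to_root(self, event_id: str) -> list[str]:
        """Event IDs from root down to (and including) *event_id*."""
        record = self._get(event_id)
        path = [record.eventID]
        while record.parentEventID in self.nodes:
            record = self.nodes[record.parentEventID]
            path.append(record.eventID)
        return path[::-1]

    def max_depth(self) -> int:
        """Number of levels (a lone root counts as 1); 0 for an empty tree."""
        if not self.nodes:
            return 0
        return 1 + max(self.depth_of(eid) for eid in self.nodes)

    def _get(self, event_id: str) -> EventRecord:
        try:
            return self.nodes[event_id]
        except KeyError:
            raise UnknownEventError(event_id) from None


def build_tree(events: list[EventRecord]) -> EventTree:
    """Index events into an :class:`EventTree`.

    Raises on duplicate eventIDs, on a parentEventID absent from the input
    (cross-archive parents are a validator WARNING, but a tree cannot be
    built over them) and on cycles.  The result is independent of input
    order up to sibling ordering.
    """
    tree = EventTree()
    for ev in events:
        if ev.eventID in tree.nodes:
            raise DuplicateEventIDError(ev.eventID)
        tree.nodes[ev.eventID] = ev
        tree.children[ev.eventID] = []
    for ev in events:
        parent = ev.parentEventID
        if not parent:
            tree.roots.append(ev.eventID)
        elif parent not in tree.nodes:
            raise DanglingParentError(parent)
        else:
            tree.children[parent].append(ev.eventID)
    _check_acyclic(tree)
    return tree


def _check_acyclic(tree: EventTree) -> None:
    state: dict[str, int] = {}  # 0 in progress, 1 done
    for start in tree.nodes:
        chain = []
        eid = start
        while eid in tree.nodes and eid not in state:
            state[eid] = 0
            chain.append(eid)
            eid = tree.nodes[eid].parentEventID
        if eid in state and state[eid] == 0:
            cycle = chain[chain.index(eid):] if eid in chain else chain
            raise CycleError(cycle + [eid])
        for c in chain:
            state[c] = 1


def resolve_inherited(tree: EventTree, event_id: str, field_name: str) -> str:
    """The event's own value for *field_name*, else the nearest ancestor's
    non-empty value, else ``""`` (absent).  Values are returned in their
    tabular text form."""
    if event_id not in tree.nodes:
        raise UnknownEventError(event_id)
    for eid in reversed(tree.path_to_root(event_id)):
        value = get_field(tree.nodes[eid], field_name)
        if value != "":
            return value
    return ""


def resolve_inherited_coordinates(tree: EventTree,
                                  event_id: str) -> tuple[str, str]:
    """Latitude and longitude resolved as a pair from the same event.

    Walking fields independently could combine a latitude from one level
    with a longitude from another, fabricating a position that was never
    recorded; here the nearest ancestor with either coordinate supplies
    both."""
    if event_id not in tree.nodes:
        raise UnknownEventError(event_id)
    for eid in reversed(tree.path_to_root(event_id)):
        lat = get_field(tree.nodes[eid], "decimalLatitude")
        lon = get_field(tree.nodes[eid], "decimalLongitude")
        if lat != "" or lon != "":
            return lat, lon
    return "", ""


def hierarchical_id(path_labels: list[str], separator: str = ":") -> str:
    """Join level labels into an eventID such as ``station5:sample1``.

    Sorting such IDs lexicographically groups events by hierarchy, which is
    why a label may not contain the separator."""
    if not path_labels:
        raise SeparatorInLabelError("path_labels must be non-empty")
    for label in path_labels:
        if separator in label:
            raise SeparatorInLabelError(
                f"label {label!r} contains separator {separator!r}")
        if not label:
            raise SeparatorInLabelError("empty label")
    return separator.join(path_labels)


def annotate_levels(tree: EventTree,
                    level_names: list[str]) -> dict[str, str]:
    """Label every event by its depth: roots get ``level_names[0]``, their
    children the next label, and so on."""
    depth = tree.max_depth()
    if depth > len(level_names):
        raise DepthExceedsLabelsError(
            f"tree depth {depth} exceeds {len(level_names)} level names")
    return {eid: level_names[tree.depth_of(eid)] for eid in tree.nodes}
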