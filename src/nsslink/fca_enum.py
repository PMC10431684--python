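"""Enumeration of formal concepts (maximal bi-cliques) of a formal context.

Concepts are produced exactly once each by a depth-first canonical
extension search: from the closure of the empty attribute set, each child
is generated by augmenting the current intent with one attribute and
closing, and a canonicity test keeps exactly one generation path per
concept.  With no pruning the search visits exactly |C| concepts.

Extents and intents are manipulated as integer bitmasks internally; the
public :class:`Concept` stores them as sorted tuples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable

from .network_io import FormalContext

__all__ = [
    "Concept",
    "derive_objects",
    "derive_attrs",
    "closure_of",
    "augment",
    "is_canonical",
    "enumerate_concepts",
    "enumerate_concepts_bruteforce",
]


@dataclass(frozen=True)
class Concept:
    """A formal concept: (extent, intent), both sorted ascending."""

    extent: tuple[int, ...]
    intent: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "extent", tuple(sorted(self.extent)))
        object.__setattr__(self, "intent", tuple(sorted(self.intent)))

    @property
    def extent_set(self) -> frozenset[int]:
        return frozenset(self.extent)

    @property
    def intent_set(self) -> frozenset[int]:
        return frozenset(self.intent)

    def leq(self, other: "Concept") -> bool:
        """Lattice order: self ⪯ other iff self.extent ⊇ other.extent."""
        return self.extent_set >= other.extent_set

    def comparable(self, other: "Concept") -> bool:
        return self.leq(other) or other.leq(self)


def _check_attrs(attrs: Iterable[int], ctx: FormalContext) -> frozenset[int]:
    attrs = frozenset(attrs)
    for m in attrs:
        if not (0 <= m < ctx.n_attributes):
            raise ValueError(f"unknown attribute ID {m}")
    return attrs


def _check_objs(objs: Iterable[int], ctx: FormalContext) -> frozenset[int]:
    objs = frozenset(objs)
    for g in objs:
        if not (0 <= g < ctx.n_objects):
            raise ValueError(f"unknown object ID {g}")
    return objs


def derive_objects(attrs: Iterable[int], ctx: FormalContext) -> frozenset[int]:
    """Objects incident to every attribute in ``attrs`` (all objects for ∅)."""
    attrs = _check_attrs(attrs, ctx)
    inc = ctx.incidence
    return frozenset(
        g for g in range(ctx.n_objects) if all((g, m) in inc for m in attrs)
    )


def derive_attrs(objs: Iterable[int], ctx: FormalContext) -> frozenset[int]:
    """Attributes incident to every object in ``objs`` (all attributes for ∅)."""
    objs = _check_objs(objs, ctx)
    inc = ctx.incidence
    return frozenset(
        m for m in range(ctx.n_attributes) if all((g, m) in inc for g in objs)
    )


def closure_of(attrs: Iterable[int], ctx: FormalContext) -> Concept:
    """The concept generated by an attribute subset via double derivation."""
    extent = derive_objects(attrs, ctx)
    intent = derive_attrs(extent, ctx)
    return Concept(tuple(extent), tuple(intent))


def augment(c: Concept, b: int, ctx: FormalContext) -> Concept:
    """Close the intent extended with one new attribute ``b`` ∉ intent."""
    if b in c.intent_set:
        raise ValueError(f"attribute {b} already in the intent")
    return closure_of(c.intent_set | {b}, ctx)


def is_canonical(parent_intent: Iterable[int], child_intent: Iterable[int]) -> bool:
    """Predecessor test: min(child − parent) > max(parent).

    True when every attribute the closure added lies beyond the largest
    attribute of the parent intent (max of the empty set is -inf, so an
    empty parent always passes).  This is the test the enumeration applies
    when the parent intent is an initial-segment closure; see
    :func:`enumerate_concepts` for the refinement used in the general case.
    """
    parent = frozenset(parent_intent)
    child = frozenset(child_intent)
    if not parent < child:
        raise ValueError("parent intent must be a proper subset of the child intent")
    return min(child - parent) > max(parent, default=-1)


def _mask_to_tuple(mask: int) -> tuple[int, ...]:
    out = []
    i = 0
    while mask:
        if mask & 1:
            out.append(i)
        mask >>= 1
        i += 1
    return tuple(out)


def enumerate_concepts(
    ctx: FormalContext,
    min_extent: int = 0,
    visitor: Callable[[Concept], None] | None = None,
) -> int:
    """Depth-first enumeration of all concepts; returns the visit count.

    ``visitor`` is called exactly once per concept, in DFS preorder: every
    root-to-node path of the recursion tree is a ⪯-chain (extent shrinks,
    intent grows).  ``min_extent > 0`` prunes every subtree whose extent is
    already smaller than the bound (sound because extents only shrink).

    Canonicity: a child closure(B ∪ {b}) generated from intent B is
    recursed into only when the attributes the closure added, beyond b
    itself, all have IDs ≥ b (prefix-preserving test with augmentation
    attributes tried in ascending order above the generator of the current
    node).  This refines the bare min/max predecessor rule of
    :func:`is_canonical` so that the enumeration stays duplicate-free and
    complete on every context, including those whose closures pull in
    low-ID attributes.
    """
    attr_masks = ctx.attr_extent_masks()
    n_att = ctx.n_attributes
    full_extent = (1 << ctx.n_objects) - 1

    def close_extent(extent: int) -> int:
        intent = 0
        for m in range(n_att):
            if extent & attr_masks[m] == extent:
                intent |= 1 << m
        return intent

    root_extent = full_extent
    root_intent = close_extent(root_extent)
    # closure of the empty attribute set: all objects, then their common attrs
    count = 0
    # stack holds (extent_mask, intent_mask, generator_attr)
    stack: list[tuple[int, int, int]] = [(root_extent, root_intent, -1)]
    while stack:
        extent, intent, y = stack.pop()
        count += 1
        if visitor is not None:
            visitor(Concept(_mask_to_tuple(extent), _mask_to_tuple(intent)))
        children = []
        for b in range(y + 1, n_att):
            if intent >> b & 1:
                continue
            child_extent = extent & attr_masks[b]
            if min_extent > 0 and child_extent.bit_count() < min_extent:
                continue
            child_intent = close_extent(child_extent)
            new_attrs = child_intent & ~intent
            if new_attrs & ((1 << b) - 1):
                continue  # a lower-ID attribute sneaked in: not the canonical path
            children.append((child_extent, child_intent, b))
        stack.extend(reversed(children))  # keep ascending-b DFS preorder
    return count


def enumerate_concepts_bruteforce(
    ctx: FormalContext, max_attributes: int = 15
) -> set[Concept]:
    """Oracle: closures of all 2^|M| attribute subsets, deduplicated.

    Refuses contexts with more than ``max_attributes`` attributes.
    """
    if ctx.n_attributes > max_attributes:
        raise ValueError(
            f"context has {ctx.n_attributes} attributes; "
            f"brute force refuses more than {max_attributes}"
        )
    attr_masks = ctx.attr_extent_masks()
    full_extent = (1 << ctx.n_objects) - 1
    concepts: set[Concept] = set()
    for subset in range(1 << ctx.n_attributes):
        extent = full_extent
        for m in range(ctx.n_attributes):
            if subset >> m & 1:
                extent &= attr_masks[m]
        intent = 0
        for m in range(ctx.n_attributes):
            if extent & attr_masks[m] == extent:
                intent |= 1 << m
        concepts.add(Concept(_mask_to_tuple(extent), _mask_to_tuple(intent)))
    return concepts
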