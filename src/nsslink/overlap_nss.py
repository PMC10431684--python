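"""Negative sample selection via overlapping maximal bi-cliques.

Comparable concepts (one extent containing the other) with large enough
components and overlap rates delimit *structural holes*: unlinked node
pairs likely to become links.  Those pairs are marked as unsafe, and
negative training samples are drawn uniformly from the remaining
unobserved pairs.

The marking walk re-uses the canonical DFS of the concept search: the
current root-to-node path is a ⪯-chain, pruned from its far end while the
extent-overlap rate with the current concept drops below the threshold;
each qualifying concept is paired with the farthest surviving ancestor.
The walk runs on the context and on its transpose, and the union of the
(fully re-checked) hole pairs is returned.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .fca_enum import Concept, _mask_to_tuple
from .network_io import BipartiteNetwork, FormalContext, to_context

__all__ = [
    "NSSParams",
    "OverlapRecord",
    "overlap_rates",
    "is_nontrivial",
    "structure_hole",
    "collect_marked_pairs",
    "marked_pairs_for_network",
    "select_negatives",
    "select_negatives_random",
]


@dataclass(frozen=True)
class NSSParams:
    """Thresholds and sampling knobs for negative sample selection.

    ``alpha``: minimum component size; ``rho``: minimum overlap rate (both
    compared with >=); ``sample_rate``: fraction of the unmarked unobserved
    pool drawn as negatives.
    """

    alpha: int = 2
    rho: float = 0.3
    sample_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [0, 1]")
        if not 0.0 <= self.sample_rate <= 1.0:
            raise ValueError("sample_rate must be in [0, 1]")


@dataclass
class OverlapRecord:
    """An ordered comparable concept pair with its sizes, rates and hole."""

    lower: Concept
    upper: Concept
    s1_lower: int = field(init=False)
    s1_upper: int = field(init=False)
    s2_lower: int = field(init=False)
    s2_upper: int = field(init=False)
    sigma1: float = field(init=False)
    sigma2: float = field(init=False)
    hole: set[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        if not self.lower.leq(self.upper):
            raise ValueError("lower must precede upper in the lattice order")
        self.s1_lower = len(self.lower.extent)
        self.s1_upper = len(self.upper.extent)
        self.s2_lower = len(self.lower.intent)
        self.s2_upper = len(self.upper.intent)
        self.sigma1, self.sigma2 = overlap_rates(self.lower, self.upper)
        self.hole = structure_hole(self.lower, self.upper)


def overlap_rates(c1: Concept, c2: Concept) -> tuple[float, float]:
    """(sigma1, sigma2) = min/max extent-size ratio and intent-size ratio.

    Symmetric in its arguments; a rate is 0 when the larger component is
    empty.  Requires the two concepts to be comparable.
    """
    if not c1.comparable(c2):
        raise ValueError("concepts are not comparable under the lattice order")

    def rate(a: int, b: int) -> float:
        hi = max(a, b)
        return (min(a, b) / hi) if hi else 0.0

    return (
        rate(len(c1.extent), len(c2.extent)),
        rate(len(c1.intent), len(c2.intent)),
    )


def is_nontrivial(rec: OverlapRecord, params: NSSParams) -> bool:
    """Both components of both concepts >= alpha and both rates >= rho."""
    sizes = (rec.s1_lower, rec.s1_upper, rec.s2_lower, rec.s2_upper)
    return min(sizes) >= params.alpha and min(rec.sigma1, rec.sigma2) >= params.rho


def structure_hole(lower: Concept, upper: Concept) -> set[tuple[int, int]]:
    """(lower.extent − upper.extent) × (upper.intent − lower.intent)."""
    if not lower.leq(upper):
        raise ValueError("lower must precede upper in the lattice order")
    objs = lower.extent_set - upper.extent_set
    attrs = upper.intent_set - lower.intent_set
    return {(g, m) for g in objs for m in attrs}


def _chain_records(
    ctx: FormalContext, alpha: int, rho: float
) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Run the chain-pruned DFS; return (lower, upper) mask pairs.

    Each element is ((lower_extent, lower_intent), (upper_extent,
    upper_intent)) with the lower concept being the farthest ancestor on
    the DFS chain whose extent-overlap rate with the upper one is still
    >= rho.  Subtrees whose extent falls below alpha are pruned (sound:
    extents only shrink going down).
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

    records: list[tuple[tuple[int, int], tuple[int, int]]] = []
    chain: list[tuple[int, int, int]] = []  # (extent_size, extent, intent)
    head = 0  # front of the surviving chain segment
    ENTER, EXIT = 0, 1
    stack: list[tuple] = [(ENTER, root_extent, root_intent, -1)]
    while stack:
        frame = stack.pop()
        if frame[0] == EXIT:
            chain.pop()
            head = frame[1]
            continue
        _, extent, intent, y = frame
        size = extent.bit_count()
        old_head = head
        # prune far ancestors: sigma1(front, current) = size/front_size
        while head < len(chain) and size < rho * chain[head][0]:
            head += 1
        chain.append((size, extent, intent))
        if size >= alpha and intent.bit_count() >= alpha:
            front = chain[head]
            records.append(((front[1], front[2]), (extent, intent)))
        stack.append((EXIT, old_head))
        children = []
        for b in range(y + 1, n_att):
            if intent >> b & 1:
                continue
            child_extent = extent & attr_masks[b]
            if child_extent.bit_count() < alpha:
                continue
            child_intent = close_extent(child_extent)
            if (child_intent & ~intent) & ((1 << b) - 1):
                continue
            children.append((ENTER, child_extent, child_intent, b))
        stack.extend(reversed(children))
    return records


def collect_marked_pairs(ctx: FormalContext, params: NSSParams) -> set[tuple[int, int]]:
    """All structural-hole pairs of non-trivial overlapping concept pairs.

    Runs the chain-pruned DFS on ``ctx`` and on its transpose (pairs from
    the transposed pass are swapped back to (object, attribute)
    orientation), re-checks the full non-triviality condition on every
    recorded pair, and unions the holes.  Incidence pairs of the context
    are never returned.
    """
    marked: set[tuple[int, int]] = set()
    for transposed, view in ((False, ctx), (True, ctx.transpose())):
        for (le, li), (ue, ui) in _chain_records(view, params.alpha, params.rho):
            if le == ue:
                continue  # the concept was its own chain front: empty hole
            lower = Concept(_mask_to_tuple(le), _mask_to_tuple(li))
            upper = Concept(_mask_to_tuple(ue), _mask_to_tuple(ui))
            rec = OverlapRecord(lower, upper)
            if not is_nontrivial(rec, params):
                continue
            if transposed:
                marked.update((m, g) for g, m in rec.hole)
            else:
                marked.update(rec.hole)
    return marked - set(ctx.incidence)


def marked_pairs_for_network(
    net: BipartiteNetwork, params: NSSParams
) -> set[tuple[str, str]]:
    """Marked (left-id, right-id) pairs of a network, via its context view."""
    ctx = to_context(net, "left-as-objects")
    marked = collect_marked_pairs(ctx, params)
    return {(net.left_nodes[g], net.right_nodes[m]) for g, m in marked}


def _draw_pool(
    net: BipartiteNetwork,
    excluded: set[tuple[str, str]],
    params: NSSParams,
) -> set[tuple[str, str]]:
    pool = sorted(
        p for p in net.all_pairs() if p not in net.present_edges and p not in excluded
    )
    n_draw = math.floor(params.sample_rate * len(pool))
    rng = random.Random(params.seed)
    return set(rng.sample(pool, n_draw))


def select_negatives(
    net: BipartiteNetwork,
    marked: set[tuple[str, str]],
    params: NSSParams,
) -> set[tuple[str, str]]:
    """Draw floor(sample_rate · |pool|) pairs from the unmarked unobserved pool.

    The pool is (V1 × V2) − present − marked; the draw is uniform without
    replacement and deterministic per seed.
    """
    return _draw_pool(net, marked, params)


def select_negatives_random(
    net: BipartiteNetwork, params: NSSParams
) -> set[tuple[str, str]]:
    """The fully random comparator: same draw with an empty marked set."""
    return _draw_pool(net, set(), params)
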