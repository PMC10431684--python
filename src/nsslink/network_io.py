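"""Bipartite network / formal context data model and text I/O.

External node identifiers are opaque strings; internally every side is
mapped to dense 0-based integer indices (attribute order defines the
canonical enumeration order used by the concept search).

Supported on-disk formats, all plain text:

* edge list TSV, 2 columns (present edges) or 3 columns (label 1/0),
  ``#``-prefixed comment lines skipped;
* Burmeister CXT formal-context files;
* dense 0/1 bi-adjacency CSV with row and column headers.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


@dataclass
class BipartiteNetwork:
    """A bipartite network G = (V1, V2, E) with optional absent-edge labels.

    ``present_edges`` are the observed links; ``absent_edges`` hold
    ground-truth absences when such labels exist (usually they do not).
    """

    left_nodes: list[str]
    right_nodes: list[str]
    present_edges: set[tuple[str, str]]
    absent_edges: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(set(self.left_nodes)) != len(self.left_nodes):
            raise ValueError("duplicate left node identifiers")
        if len(set(self.right_nodes)) != len(self.right_nodes):
            raise ValueError("duplicate right node identifiers")
        left = set(self.left_nodes)
        right = set(self.right_nodes)
        for u, v in self.present_edges | self.absent_edges:
            if u not in left or v not in right:
                raise ValueError(f"edge ({u!r}, {v!r}) has an unknown endpoint")
        overlap = self.present_edges & self.absent_edges
        if overlap:
            raise ValueError(f"edges labeled both present and absent: {sorted(overlap)[:5]}")

    @property
    def n_left(self) -> int:
        return len(self.left_nodes)

    @property
    def n_right(self) -> int:
        return len(self.right_nodes)

    def left_index(self) -> dict[str, int]:
        return {u: i for i, u in enumerate(self.left_nodes)}

    def right_index(self) -> dict[str, int]:
        return {v: j for j, v in enumerate(self.right_nodes)}

    def all_pairs(self) -> Iterable[tuple[str, str]]:
        for u in self.left_nodes:
            for v in self.right_nodes:
                yield (u, v)

    def unobserved_pairs(self) -> Iterable[tuple[str, str]]:
        """All pairs that are not observed present links."""
        for p in self.all_pairs():
            if p not in self.present_edges:
                yield p

    def copy(self) -> "BipartiteNetwork":
        return BipartiteNetwork(
            list(self.left_nodes),
            list(self.right_nodes),
            set(self.present_edges),
            set(self.absent_edges),
        )


@dataclass(frozen=True)
class FormalContext:
    """A formal context K = (G, M, Y) with consecutive integer IDs.

    Objects are 0..n_objects-1, attributes 0..n_attributes-1; ``incidence``
    is the relation Y as a set of (object, attribute) pairs.
    """

    n_objects: int
    n_attributes: int
    incidence: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        for g, m in self.incidence:
            if not (0 <= g < self.n_objects and 0 <= m < self.n_attributes):
                raise ValueError(f"incidence pair ({g}, {m}) out of range")

    def transpose(self) -> "FormalContext":
        return FormalContext(
            self.n_attributes,
            self.n_objects,
            frozenset((m, g) for g, m in self.incidence),
        )

    def attr_extent_masks(self) -> list[int]:
        """Bitmask of objects incident to each attribute (bit g set iff (g, m) in Y)."""
        masks = [0] * self.n_attributes
        for g, m in self.incidence:
            masks[m] |= 1 << g
        return masks

    def object_intent_masks(self) -> list[int]:
        masks = [0] * self.n_objects
        for g, m in self.incidence:
            masks[g] |= 1 << m
        return masks


@dataclass
class SplitResult:
    """Train/target split: the input network with hidden positives removed."""

    input_network: BipartiteNetwork
    target_network: BipartiteNetwork
    hidden_positive_edges: set[tuple[str, str]]


# ---------------------------------------------------------------------------
# Edge lists


def read_edgelist(path: str | Path, has_labels: bool | None = None) -> BipartiteNetwork:
    """Read a 2- or 3-column TSV edge list.

    Nodes are collected in first-appearance order; duplicate rows collapse.
    With 3 columns, the third must be 1 (present) or 0 (absent); a pair
    labeled both ways raises :class:`ParseError`.  When ``has_labels`` is
    None the column count of the first data row decides.
    """
    left: list[str] = []
    right: list[str] = []
    seen_left: set[str] = set()
    seen_right: set[str] = set()
    present: set[tuple[str, str]] = set()
    absent: set[tuple[str, str]] = set()

    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if has_labels is None:
                has_labels = len(cols) == 3
            want = 3 if has_labels else 2
            if len(cols) != want:
                raise ParseError(f"{path}: line {lineno}: expected {want} columns, got {len(cols)}")
            u, v = cols[0], cols[1]
            if not u or not v:
                raise ParseError(f"{path}: line {lineno}: empty node identifier")
            if has_labels:
                if cols[2] not in ("0", "1"):
                    raise ParseError(f"{path}: line {lineno}: label must be 0 or 1, got {cols[2]!r}")
                label = cols[2] == "1"
            else:
                label = True
            pair = (u, v)
            if label:
                if pair in absent:
                    raise ParseError(f"{path}: line {lineno}: pair {pair} labeled both 0 and 1")
                present.add(pair)
            else:
                if pair in present:
                    raise ParseError(f"{path}: line {lineno}: pair {pair} labeled both 0 and 1")
                absent.add(pair)
            if u not in seen_left:
                seen_left.add(u)
                left.append(u)
            if v not in seen_right:
                seen_right.add(v)
                right.append(v)

    return BipartiteNetwork(left, right, present, absent)


def write_edgelist(net: BipartiteNetwork, path: str | Path, with_labels: bool = False) -> None:
    """Write the network back as a TSV edge list (deterministic row order)."""
    with open(path, "w", encoding="utf-8") as fh:
        li = net.left_index()
        ri = net.right_index()

        def key(pair: tuple[str, str]) -> tuple[int, int]:
            return (li[pair[0]], ri[pair[1]])

        if with_labels:
            rows = [(p, 1) for p in net.present_edges] + [(p, 0) for p in net.absent_edges]
            for pair, label in sorted(rows, key=lambda r: key(r[0])):
                fh.write(f"{pair[0]}\t{pair[1]}\t{label}\n")
        else:
            for pair in sorted(net.present_edges, key=key):
                fh.write(f"{pair[0]}\t{pair[1]}\n")


# ---------------------------------------------------------------------------
# Formal contexts


def to_context(net: BipartiteNetwork, orientation: str = "left-as-objects") -> FormalContext:
    """View the network as a formal context.

    ``left-as-objects`` maps V1 to objects and V2 to attributes;
    ``right-as-objects`` is the transpose (the second enumeration pass of
    the marking algorithm runs on it).
    """
    li = net.left_index()
    ri = net.right_index()
    if orientation == "left-as-objects":
        inc = frozenset((li[u], ri[v]) for u, v in net.present_edges)
        return FormalContext(net.n_left, net.n_right, inc)
    if orientation == "right-as-objects":
        inc = frozenset((ri[v], li[u]) for u, v in net.present_edges)
        return FormalContext(net.n_right, net.n_left, inc)
    raise ValueError(f"unknown orientation {orientation!r}")


def context_to_network(ctx: FormalContext) -> BipartiteNetwork:
    """Context as a network with stringified integer IDs (objects on the left)."""
    return BipartiteNetwork(
        [f"g{i}" for i in range(ctx.n_objects)],
        [f"m{j}" for j in range(ctx.n_attributes)],
        {(f"g{g}", f"m{m}") for g, m in ctx.incidence},
    )


def read_cxt(path: str | Path) -> tuple[FormalContext, list[str], list[str]]:
    """Read a Burmeister CXT file; returns (context, object names, attribute names)."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    body = [ln for ln in lines if ln.strip() != ""]
    if not body or body[0].strip() != "B":
        raise ParseError(f"{path}: not a Burmeister CXT file (missing 'B' header)")
    try:
        n_obj = int(body[1])
        n_att = int(body[2])
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}: bad object/attribute counts") from exc
    names = body[3 : 3 + n_obj + n_att]
    if len(names) < n_obj + n_att:
        raise ParseError(f"{path}: truncated name section")
    objects = names[:n_obj]
    attributes = names[n_obj:]
    rows = body[3 + n_obj + n_att :]
    if len(rows) < n_obj:
        raise ParseError(f"{path}: truncated incidence section")
    incidence = set()
    for g, row in enumerate(rows[:n_obj]):
        if len(row) != n_att:
            raise ParseError(f"{path}: incidence row {g} has length {len(row)}, expected {n_att}")
        for m, ch in enumerate(row):
            if ch in ("X", "x"):
                incidence.add((g, m))
            elif ch != ".":
                raise ParseError(f"{path}: incidence row {g}: unexpected character {ch!r}")
    return FormalContext(n_obj, n_att, frozenset(incidence)), objects, attributes


def write_cxt(
    ctx: FormalContext,
    path: str | Path,
    objects: Sequence[str] | None = None,
    attributes: Sequence[str] | None = None,
) -> None:
    objects = list(objects) if objects is not None else [f"g{i}" for i in range(ctx.n_objects)]
    attributes = (
        list(attributes) if attributes is not None else [f"m{j}" for j in range(ctx.n_attributes)]
    )
    inc = ctx.incidence
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("B\n\n")
        fh.write(f"{ctx.n_objects}\n{ctx.n_attributes}\n\n")
        for name in objects:
            fh.write(name + "\n")
        for name in attributes:
            fh.write(name + "\n")
        for g in range(ctx.n_objects):
            fh.write("".join("X" if (g, m) in inc else "." for m in range(ctx.n_attributes)) + "\n")


# ---------------------------------------------------------------------------
# Dense bi-adjacency CSV


def read_biadjacency_csv(path: str | Path) -> BipartiteNetwork:
    """Read a dense 0/1 matrix CSV with row and column headers."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return BipartiteNetwork([], [], set())
    header = lines[0].split(",")
    right = header[1:]
    left: list[str] = []
    present: set[tuple[str, str]] = set()
    for lineno, ln in enumerate(lines[1:], start=2):
        cols = ln.split(",")
        if len(cols) != len(right) + 1:
            raise ParseError(f"{path}: line {lineno}: expected {len(right) + 1} columns")
        left.append(cols[0])
        for v, cell in zip(right, cols[1:]):
            if cell == "1":
                present.add((cols[0], v))
            elif cell != "0":
                raise ParseError(f"{path}: line {lineno}: cell must be 0 or 1, got {cell!r}")
    return BipartiteNetwork(left, right, present)


def write_biadjacency_csv(net: BipartiteNetwork, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("," + ",".join(net.right_nodes) + "\n")
        for u in net.left_nodes:
            cells = ("1" if (u, v) in net.present_edges else "0" for v in net.right_nodes)
            fh.write(u + "," + ",".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Masking split and prediction files


def mask_positives(net: BipartiteNetwork, hide_fraction: float, seed: int) -> SplitResult:
    """Hide a uniformly chosen fraction of present links from a copy of ``net``.

    Exactly round-half-up(hide_fraction * |present|) edges are removed; the
    copy's absent labels are emptied (no ground truth for negatives in the
    input).  Deterministic for a fixed seed.
    """
    if not 0 <= hide_fraction < 1:
        raise ValueError(f"hide_fraction must be in [0, 1), got {hide_fraction}")
    if not net.present_edges:
        raise ValueError("network has no present edges to mask")
    n_hide = math.floor(hide_fraction * len(net.present_edges) + 0.5)
    rng = random.Random(seed)
    hidden = set(rng.sample(sorted(net.present_edges), n_hide))
    input_net = BipartiteNetwork(
        list(net.left_nodes),
        list(net.right_nodes),
        net.present_edges - hidden,
        set(),
    )
    return SplitResult(input_net, net.copy(), hidden)


def write_predictions(
    scores: Iterable[tuple[str, str, float]], path: str | Path
) -> None:
    """Write scored pairs as a TSV sorted by descending score.

    Ties break by (left-id, right-id).  NaN scores are rejected.
    """
    rows = []
    for u, v, s in scores:
        s = float(s)
        if math.isnan(s) or math.isinf(s):
            raise ValueError(f"non-finite score for pair ({u!r}, {v!r}): {s}")
        rows.append((u, v, s))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("left\tright\tscore\n")
        for u, v, s in rows:
            fh.write(f"{u}\t{v}\t{s:.12g}\n")


def read_predictions(path: str | Path) -> list[tuple[str, str, float]]:
    rows: list[tuple[str, str, float]] = []
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() and header.split("\t")[:2] != ["left", "right"]:
            raise ParseError(f"{path}: missing 'left\\tright\\tscore' header")
        for lineno, ln in enumerate(fh, start=2):
            if not ln.strip():
                continue
            cols = ln.rstrip("\n").split("\t")
            if len(cols) != 3:
                raise ParseError(f"{path}: line {lineno}: expected 3 columns")
            rows.append((cols[0], cols[1], float(cols[2])))
    return rows
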