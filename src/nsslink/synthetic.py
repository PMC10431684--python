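"""Seeded generator of planted-structure bipartite networks.

Blocks (full bi-cliques) are laid out in a chain, each sharing a fixed
fraction of its nodes with the next block on both sides.  The chain
topology gives analytically known structural holes between consecutive
blocks, which the marking stage must recover on noise-free instances.
Background noise edges, ground-truth absent labels, and positive-link
masking emulate the experimental regimes the method targets.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

from .network_io import BipartiteNetwork, SplitResult, mask_positives
from .overlap_nss import NSSParams

__all__ = [
    "PlantedConfig",
    "Block",
    "planted_blocks",
    "generate_planted",
    "known_hole_pairs",
    "suitable_nss_params",
]


@dataclass(frozen=True)
class PlantedConfig:
    n_left: int = 60
    n_right: int = 80
    n_blocks: int = 6
    block_size_range: tuple[int, int] = (8, 10)
    overlap_fraction: float = 0.4
    noise_rate: float = 0.0
    hide_fraction: float = 0.2
    hole_link_fraction: float = 0.0
    absent_label_rate: float = 0.3
    seed: int = 0
    clean_holes: bool = True

    def __post_init__(self) -> None:
        for name in (
            "overlap_fraction",
            "noise_rate",
            "hide_fraction",
            "hole_link_fraction",
            "absent_label_rate",
        ):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.hide_fraction >= 1.0:
            raise ValueError("hide_fraction must be < 1")
        lo, hi = self.block_size_range
        if not 1 <= lo <= hi:
            raise ValueError("block_size_range must satisfy 1 <= min <= max")
        if hi > min(self.n_left, self.n_right):
            raise ValueError("block sizes exceed the side sizes")
        if self.n_blocks < 1:
            raise ValueError("need at least one block")


@dataclass(frozen=True)
class Block:
    left: frozenset[int]
    right: frozenset[int]


def planted_blocks(cfg: PlantedConfig) -> list[Block]:
    """Deterministic chain layout of the planted blocks (index sets).

    Block t shares round(overlap_fraction * min(size_t, size_{t+1})) nodes
    with block t+1 on each side.  Raises when the chain does not fit.
    """
    rng = random.Random(cfg.seed)
    lo, hi = cfg.block_size_range
    left_sizes = [rng.randint(lo, hi) for _ in range(cfg.n_blocks)]
    right_sizes = [rng.randint(lo, hi) for _ in range(cfg.n_blocks)]

    def starts(sizes: list[int], side_total: int, label: str) -> list[int]:
        pos = [0]
        for t in range(1, len(sizes)):
            ov = round(cfg.overlap_fraction * min(sizes[t - 1], sizes[t]))
            pos.append(pos[-1] + sizes[t - 1] - ov)
        if pos[-1] + sizes[-1] > side_total:
            raise ValueError(
                f"infeasible block sizes: chain needs {pos[-1] + sizes[-1]} "
                f"{label} nodes, only {side_total} available"
            )
        return pos

    left_pos = starts(left_sizes, cfg.n_left, "left")
    right_pos = starts(right_sizes, cfg.n_right, "right")
    return [
        Block(
            frozenset(range(left_pos[t], left_pos[t] + left_sizes[t])),
            frozenset(range(right_pos[t], right_pos[t] + right_sizes[t])),
        )
        for t in range(cfg.n_blocks)
    ]


def _hole_index_pairs(blocks: list[Block]) -> set[tuple[int, int]]:
    holes: set[tuple[int, int]] = set()
    for a, b in zip(blocks, blocks[1:]):
        if not (a.left & b.left) or not (a.right & b.right):
            continue  # disjoint blocks: no comparable overlapping concepts
        holes |= {(g, m) for g in a.left - b.left for m in b.right - a.right}
        holes |= {(g, m) for g in b.left - a.left for m in a.right - b.right}
    return holes


def generate_planted(
    cfg: PlantedConfig,
) -> tuple[BipartiteNetwork, BipartiteNetwork, SplitResult]:
    """Build (target, input, split) with planted overlapping bi-cliques.

    The target carries present edges (blocks, plus a fraction of the
    inter-block structural-hole pairs promoted to true-but-never-observed
    links, plus noise) and a fraction of the remaining non-edges labeled as
    ground-truth absents.  The input loses every promoted hole link and a
    ``hide_fraction`` mask of the other positives, and has no absent
    labels.  Fully deterministic per seed.
    """
    blocks = planted_blocks(cfg)
    left_nodes = [f"u{i}" for i in range(cfg.n_left)]
    right_nodes = [f"v{j}" for j in range(cfg.n_right)]

    observed_idx: set[tuple[int, int]] = set()
    for blk in blocks:
        observed_idx |= {(g, m) for g in blk.left for m in blk.right}

    rng = random.Random(cfg.seed + 1)
    # structural-hole pairs promoted to hidden true links: the regime the
    # marking stage is built for (holes between overlapping clusters tend
    # to be real links that simply went unobserved)
    hole_links: set[tuple[int, int]] = set()
    if cfg.hole_link_fraction > 0:
        for pair in sorted(_hole_index_pairs(blocks)):
            if rng.random() < cfg.hole_link_fraction:
                hole_links.add(pair)

    if cfg.noise_rate > 0:
        forbidden = _hole_index_pairs(blocks) if cfg.clean_holes else hole_links
        for g in range(cfg.n_left):
            for m in range(cfg.n_right):
                if (g, m) in observed_idx or (g, m) in forbidden:
                    continue
                if rng.random() < cfg.noise_rate:
                    observed_idx.add((g, m))

    present_idx = observed_idx | hole_links
    absent_idx: set[tuple[int, int]] = set()
    if cfg.absent_label_rate > 0:
        for g in range(cfg.n_left):
            for m in range(cfg.n_right):
                if (g, m) not in present_idx and rng.random() < cfg.absent_label_rate:
                    absent_idx.add((g, m))

    target = BipartiteNetwork(
        left_nodes,
        right_nodes,
        {(left_nodes[g], right_nodes[m]) for g, m in present_idx},
        {(left_nodes[g], right_nodes[m]) for g, m in absent_idx},
    )
    observed = BipartiteNetwork(
        left_nodes,
        right_nodes,
        {(left_nodes[g], right_nodes[m]) for g, m in observed_idx},
    )
    split = mask_positives(observed, cfg.hide_fraction, cfg.seed + 2)
    split = SplitResult(
        split.input_network,
        target,
        target.present_edges - split.input_network.present_edges,
    )
    return target, split.input_network, split


def known_hole_pairs(cfg: PlantedConfig, split: SplitResult | None = None) -> set[tuple[str, str]]:
    """Analytic structural-hole pairs between consecutive planted blocks.

    Only defined for noise-free instances (with noise the holes are no
    longer analytic).  Both orientations of each consecutive pair are
    included: exclusive-left-of-one × exclusive-right-of-the-other.
    """
    if cfg.noise_rate > 0:
        raise ValueError("known_hole_pairs requires noise_rate == 0")
    blocks = planted_blocks(cfg)
    return {(f"u{g}", f"v{m}") for g, m in _hole_index_pairs(blocks)}


def suitable_nss_params(
    cfg: PlantedConfig, sample_rate: float = 0.5, seed: int = 0
) -> NSSParams:
    """Thresholds guaranteed to recover every analytic hole on a clean instance.

    alpha is capped by the smallest planted overlap and component;
    rho must exceed the overlap rate of the whole object set with any
    planted concept (so the lattice root is always pruned from the chains)
    while staying below the smallest within-chain overlap rate.  Raises if
    the realized layout admits no such window.
    """
    if cfg.noise_rate > 0:
        raise ValueError("suitable_nss_params requires noise_rate == 0")
    blocks = planted_blocks(cfg)
    alpha_cap = math.inf
    rho_hi = 1.0
    rho_lo = 0.0
    for a, b in zip(blocks, blocks[1:]):
        oa, ob = len(a.left & b.left), len(a.right & b.right)
        if oa == 0 or ob == 0:
            continue
        sa1, sa2 = len(a.left), len(a.right)
        sb1, sb2 = len(b.left), len(b.right)
        alpha_cap = min(alpha_cap, oa, ob, sa1, sa2, sb1, sb2)
        union_l = sa1 + sb1 - oa
        union_r = sa2 + sb2 - ob
        rho_hi = min(
            rho_hi,
            oa / sa1, oa / sb1, ob / sa2, ob / sb2,
            sa1 / union_l, sb1 / union_l, sa2 / union_r, sb2 / union_r,
        )
        rho_lo = max(rho_lo, union_l / cfg.n_left, union_r / cfg.n_right)
    if not math.isfinite(alpha_cap):
        raise ValueError("no overlapping consecutive blocks in the layout")
    if rho_lo >= rho_hi:
        raise ValueError(
            f"no feasible rho window: need rho in ({rho_lo:.3f}, {rho_hi:.3f}]"
        )
    rho = rho_hi  # tightest threshold that still keeps every planted chain
    alpha = min(2, int(alpha_cap))
    return NSSParams(alpha=alpha, rho=rho, sample_rate=sample_rate, seed=seed)
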