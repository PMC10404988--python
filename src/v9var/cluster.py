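"""Two OTU definitions: single-linkage d=1 "swarms" and 97% centroid clusters.

Swarms are the connected components of the graph joining unique sequences
at Levenshtein distance <= 1, seeded from the most abundant member; the
fastidious refinement grafts low-mass swarms (mass < 3 by default) onto the
highest-mass swarm reachable through one virtual intermediate (total
distance <= 2).  Neighbor candidates are generated with the
deletion-signature trick (each sequence indexed under itself and all of its
single-deletion variants) rather than all-pairs comparison; the all-pairs
graph remains the test oracle.

Centroid clustering is the greedy abundance-ordered pass at a 97% global
identity threshold.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import pandas as pd

from .align import ScoringScheme, global_identity
from .extract import Barcode

__all__ = [
    "Swarm",
    "Cluster97",
    "SwarmConfig",
    "swarm_d1",
    "centroid_cluster",
    "env_prefilter",
]


@dataclass
class SwarmConfig:
    d: int = 1
    fastidious: bool = True
    fastidious_boundary: int = 3  # swarms with mass < boundary are graft candidates

    def __post_init__(self):
        if self.d != 1:
            raise ValueError("only d=1 clustering is supported")
        if self.fastidious_boundary < 2:
            raise ValueError("fastidious boundary must be >= 2")


@dataclass
class Swarm:
    seed: Barcode
    members: list[Barcode]
    mass: int

    def __contains__(self, sequence: str) -> bool:
        return any(m.sequence == sequence for m in self.members)


@dataclass
class Cluster97:
    centroid: Barcode
    members: list[Barcode]


def _deletion_keys(seq: str):
    yield seq
    for i in range(len(seq)):
        yield seq[:i] + seq[i + 1 :]


def _within_one(a: str, b: str) -> bool:
    """Levenshtein distance <= 1, by direct structural check."""
    if a == b:
        return True
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:
        return sum(1 for x, y in zip(a, b) if x != y) <= 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # a is one shorter: b with one deletion must equal a
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1 :]


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def swarm_d1(barcodes: list[Barcode], cfg: SwarmConfig | None = None) -> list[Swarm]:
    """Single-linkage clustering at one difference, with optional grafting.

    Input must be dereplicated (unique sequences).  Output is canonical:
    sorted by mass descending, ties by seed sequence; member lists sorted by
    count descending then sequence, so permuting the input does not change
    the result.
    """
    cfg = cfg or SwarmConfig()
    if not barcodes:
        return []
    items = sorted(barcodes, key=lambda b: (-b.count, b.sequence))
    seqs = [b.sequence for b in items]
    if len(set(seqs)) != len(seqs):
        raise ValueError("swarm_d1 requires dereplicated (unique) sequences")

    index: dict[str, list[int]] = defaultdict(list)
    for i, s in enumerate(seqs):
        for key in _deletion_keys(s):
            index[key].append(i)
    uf = _UnionFind(len(seqs))
    for bucket in index.values():
        if len(bucket) < 2:
            continue
        for pos, i in enumerate(bucket):
            for j in bucket[pos + 1 :]:
                if uf.find(i) != uf.find(j) and _within_one(seqs[i], seqs[j]):
                    uf.union(i, j)

    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(len(seqs)):
        groups[uf.find(i)].append(i)

    swarms = []
    for members_idx in groups.values():
        members = sorted(
            (items[i] for i in members_idx), key=lambda b: (-b.count, b.sequence)
        )
        swarms.append(Swarm(members[0], members, sum(b.count for b in members)))

    if cfg.fastidious:
        swarms = _graft_light_swarms(swarms, cfg.fastidious_boundary)
    swarms.sort(key=lambda s: (-s.mass, s.seed.sequence))
    return swarms


def _graft_light_swarms(swarms: list[Swarm], boundary: int) -> list[Swarm]:
    """Graft swarms with mass < boundary onto reachable heavy swarms.

    A light swarm is reachable when any of its members is within Levenshtein
    distance 2 of any heavy-swarm member (one virtual intermediate).  It
    grafts onto the highest-mass such heavy swarm; unreachable light swarms
    stay standalone.  Assignments are computed against the original heavy
    swarms, so grafting cannot chain light swarms together.
    """
    heavy = [s for s in swarms if s.mass >= boundary]
    light = [s for s in swarms if s.mass < boundary]
    if not heavy or not light:
        return swarms
    heavy.sort(key=lambda s: (-s.mass, s.seed.sequence))
    grafts: list[tuple[Swarm, Swarm]] = []
    kept_light = []
    for ls in light:
        target = None
        for hs in heavy:  # highest-mass first
            linked = any(
                edlib.align(a.sequence, b.sequence, mode="NW", k=2)["editDistance"] >= 0
                for a in ls.members
                for b in hs.members
            )
            if linked:
                target = hs
                break
        if target is None:
            kept_light.append(ls)
        else:
            grafts.append((ls, target))
    for ls, hs in grafts:
        hs.members.extend(ls.members)
        hs.mass += ls.mass
        hs.members.sort(key=lambda b: (-b.count, b.sequence))
        hs.seed = hs.members[0]
    return heavy + kept_light


def centroid_cluster(
    barcodes: list[Barcode],
    min_identity: float = 0.97,
    scoring: ScoringScheme | None = None,
) -> list[Cluster97]:
    """Greedy abundance-ordered centroid clustering at 97% global identity.

    Sequences are visited in decreasing count order (ties lexicographic);
    each joins the first already-created centroid with identity >= the
    threshold, else founds a new cluster.
    """
    clusters: list[Cluster97] = []
    for b in sorted(barcodes, key=lambda b: (-b.count, b.sequence)):
        for c in clusters:
            if global_identity(b.sequence, c.centroid.sequence, scoring) >= min_identity:
                c.members.append(b)
                break
        else:
            clusters.append(Cluster97(b, [b]))
    return clusters


def env_prefilter(
    table: pd.DataFrame, min_samples: int = 2, min_reads: int = 3
) -> pd.DataFrame:
    """Occupancy/abundance prefilter for environmental barcode tables.

    Retain a barcode (row) iff it occurs in at least ``min_samples`` samples
    and its total count is at least ``min_reads`` — i.e. with the defaults,
    present in more than one sample with more than two reads.
    """
    if table.shape[1] < 1:
        raise ValueError("table must have at least one sample column")
    occupancy = (table > 0).sum(axis=1)
    total = table.sum(axis=1)
    return table.loc[(occupancy >= min_samples) & (total >= min_reads)]
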