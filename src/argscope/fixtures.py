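"""Test-input generators: a hand-built canonical ARG and a seeded
backward-time Wright–Fisher simulator with recombination.

The simulator tracks ancestral genome segments of ``n_samples`` haploid
lineages backwards through discrete generations in a population of fixed
size.  Each generation, every lineage is cut at Poisson-distributed
crossover points and each resulting chunk is assigned to a uniformly chosen
parent; chunks landing on the same parent coalesce wherever their ancestral
material overlaps, creating a new node and the corresponding edges.  An
optional selective-sweep caricature biases the parent choice of chunks
covering a focal position towards a single lineage, concentrating recent
coalescence at the centre of the genome.  This is a deliberately simple
generator for producing valid, realistic desk-scale ARGs — not a calibrated
population-genetic model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ts_model import (
    NODE_IS_SAMPLE,
    EdgeTable,
    MutationTable,
    NodeTable,
    SiteTable,
    TreeSequenceData,
)


def canonical_example() -> TreeSequenceData:
    """A 5-node, 7-edge, 2-tree ARG over [0, 10) used throughout the tests.

    Three samples at time 0; internal nodes 3 (t=1) and 4 (t=2).  The local
    tree on [0, 5) is ((0,1)3,2)4 and on [5, 10) is ((0,2)3,1)4.  Two sites
    carry three mutations, one of which (m2) chains onto m0.  All mutation
    times are unknown.
    """
    return TreeSequenceData(
        sequence_length=10.0,
        nodes=NodeTable(
            time=[0.0, 0.0, 0.0, 1.0, 2.0],
            flags=[NODE_IS_SAMPLE] * 3 + [0, 0],
            population=[-1] * 5,
            individual=[-1] * 5,
        ),
        edges=EdgeTable(
            left=[0, 0, 5, 5, 0, 5, 0],
            right=[5, 5, 10, 10, 5, 10, 10],
            parent=[3, 3, 3, 3, 4, 4, 4],
            child=[0, 1, 0, 2, 2, 1, 3],
        ),
        sites=SiteTable(position=[2.0, 7.0], ancestral_state=["A", "G"]),
        mutations=MutationTable(
            site=[0, 1, 0],
            node=[3, 0, 0],
            derived_state=["T", "C", "A"],
            parent=[-1, -1, 0],
            time=[np.nan, np.nan, np.nan],
        ),
        metadata={"name": "canonical_example"},
    )


@dataclass
class SimParams:
    """Parameters of the Wright–Fisher fixture simulator.

    recombination_rate and mutation_rate are per-genome-per-generation
    expected event counts.  ``sweep`` is an optional (position, strength)
    pair: chunks of ancestral material covering ``position`` pick the focal
    parent (individual 0) with probability ``strength`` instead of
    uniformly.  ``pop_size`` defaults to twice the sample size so that most
    lineages coalesce within the default generation budget.
    """

    n_samples: int
    sequence_length: float = 100.0
    n_generations: int = 200
    recombination_rate: float = 1.0
    mutation_rate: float = 1.0
    sweep: tuple[float, float] | None = None
    seed: int = 0
    pop_size: int | None = None

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")
        if min(self.recombination_rate, self.mutation_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.pop_size is None:
            self.pop_size = 2 * self.n_samples


# A lineage is a list of (left, right, node, n_desc) segments, sorted and
# disjoint; n_desc is the number of samples the segment is ancestral to.


def _split_chunks(segments, cuts):
    """Split a lineage's segments at crossover positions into chunks."""
    bounds = [-np.inf] + sorted(cuts) + [np.inf]
    chunks = []
    for lo, hi in zip(bounds, bounds[1:]):
        chunk = []
        for left, right, node, nd in segments:
            l, r = max(left, lo), min(right, hi)
            if l < r:
                chunk.append((l, r, node, nd))
        if chunk:
            chunks.append(chunk)
    return chunks


def _merge(chunks, time, next_node, n_samples, nodes_time, edges):
    """Coalesce the chunk lists arriving at one parent individual.

    Returns (surviving lineage or None, next free node id).  Wherever two
    or more segments overlap, a single new node (per parent, per
    generation) becomes their parent over the overlap, and the merged
    segment carries the summed descendant count; intervals ancestral to
    every sample are fully coalesced and dropped from further tracking.
    """
    if len(chunks) == 1:
        return chunks[0], next_node
    segs = [s for chunk in chunks for s in chunk]
    points = np.unique([p for s in segs for p in (s[0], s[1])])
    new_node = -1
    out = []
    for lo, hi in zip(points, points[1:]):
        cover = [s for s in segs if s[0] <= lo and s[1] >= hi]
        if not cover:
            continue
        if len(cover) == 1:
            left, right, node, nd = cover[0]
            out.append((lo, hi, node, nd))
        else:
            if new_node == -1:
                new_node = next_node
                next_node += 1
                nodes_time.append(float(time))
            nd = 0
            for _, _, node, d in cover:
                edges.append((lo, hi, new_node, node))
                nd += d
            if nd < n_samples:  # not yet the MRCA here: keep tracking
                out.append((lo, hi, new_node, nd))
    # stitch adjacent pieces of the same node back together
    merged = []
    for seg in out:
        if merged and merged[-1][2] == seg[2] and merged[-1][1] == seg[0]:
            prev = merged.pop()
            merged.append((prev[0], seg[1], seg[2], seg[3]))
        else:
            merged.append(seg)
    return (merged or None), next_node


def _squash_edges(edges, nodes_time):
    """Canonicalize raw edge tuples: merge abutting same-pair intervals."""
    if not edges:
        return np.empty((4, 0))
    arr = sorted(edges, key=lambda e: (e[2], e[3], e[0]))
    squashed = [list(arr[0])]
    for left, right, parent, child in arr[1:]:
        last = squashed[-1]
        if last[2] == parent and last[3] == child and last[1] == left:
            last[1] = right
        else:
            squashed.append([left, right, parent, child])
    sq = np.asarray(squashed, np.float64).T
    return sq


def simulate_wf_arg(params: SimParams) -> TreeSequenceData:
    """Run the backward Wright–Fisher simulation; returns a valid ARG.

    Identical parameters (including seed) give bit-identical tables.
    Lineages that have not coalesced after ``n_generations`` simply stop,
    leaving multiple local roots — permitted, not an error.
    """
    rng = np.random.default_rng(params.seed)
    n, L = params.n_samples, params.sequence_length
    nodes_time = [0.0] * n
    lineages = [[(0.0, L, i, 1)] for i in range(n)]
    edges: list[tuple] = []
    next_node = n

    for gen in range(1, params.n_generations + 1):
        if not lineages:
            break
        buckets: dict[int, list] = {}
        for segs in lineages:
            k = rng.poisson(params.recombination_rate)
            cuts = list(rng.uniform(0.0, L, size=k)) if k else []
            for chunk in _split_chunks(segs, cuts):
                parent = int(rng.integers(params.pop_size))
                if params.sweep is not None:
                    pos, strength = params.sweep
                    if chunk[0][0] <= pos < chunk[-1][1]:
                        if rng.random() < strength:
                            parent = 0
                buckets.setdefault(parent, []).append(chunk)
        lineages = []
        for parent in sorted(buckets):
            survivor, next_node = _merge(
                buckets[parent], gen, next_node, n, nodes_time, edges
            )
            if survivor:
                lineages.append(survivor)

    edge_arr = _squash_edges(edges, nodes_time)
    num_nodes = next_node
    flags = np.zeros(num_nodes, np.int64)
    flags[:n] = NODE_IS_SAMPLE

    # drop mutations uniformly on edge area at the per-genome rate
    left, right, parent, child = edge_arr
    if len(left):
        bl = np.asarray(nodes_time)[parent.astype(int)] - np.asarray(
            nodes_time
        )[child.astype(int)]
        area = (right - left) * bl
        lam = params.mutation_rate * area / L
        counts = rng.poisson(lam)
        positions, mut_node = [], []
        for i in np.flatnonzero(counts):
            pos = rng.uniform(left[i], right[i], size=counts[i])
            positions.extend(pos)
            mut_node.extend([int(child[i])] * int(counts[i]))
    else:
        positions, mut_node = [], []

    positions = np.asarray(positions, np.float64)
    mut_node = np.asarray(mut_node, np.int64)
    order = np.argsort(positions, kind="stable")
    positions, mut_node = positions[order], mut_node[order]
    # continuous positions collide with probability ~0; drop any duplicate
    # so that each site carries exactly one mutation
    keep = np.ones(len(positions), bool)
    keep[1:] = positions[1:] > positions[:-1]
    positions, mut_node = positions[keep], mut_node[keep]

    bases = np.array(list("ACGT"))
    anc = bases[rng.integers(4, size=len(positions))]
    der = bases[
        (np.char.find("ACGT", anc.astype("U1"))
         + 1 + rng.integers(3, size=len(positions))) % 4
    ] if len(positions) else np.empty(0, "U1")

    ts = TreeSequenceData(
        sequence_length=L,
        nodes=NodeTable(
            time=np.asarray(nodes_time),
            flags=flags,
            population=np.full(num_nodes, -1, np.int64),
            individual=np.full(num_nodes, -1, np.int64),
        ),
        edges=EdgeTable(left, right, parent.astype(np.int64),
                        child.astype(np.int64)),
        sites=SiteTable(positions, anc.astype(object)),
        mutations=MutationTable(
            site=np.arange(len(positions), dtype=np.int64),
            node=mut_node,
            derived_state=der.astype(object),
            parent=np.full(len(positions), -1, np.int64),
            time=np.full(len(positions), np.nan),
        ),
        metadata={"simulator": "wf_backward", "params": repr(params)},
    )
    return ts


def sweep_example(
    n_samples: int = 50,
    sequence_length: float = 1000.0,
    strength: float = 0.9,
    seed: int = 1,
) -> TreeSequenceData:
    """Strong-sweep fixture: excess recent coalescence at the genome centre,
    producing the characteristic wedge of missing edges in an edges view."""
    return simulate_wf_arg(
        SimParams(
            n_samples=n_samples,
            sequence_length=sequence_length,
            n_generations=400,
            recombination_rate=2.0,
            mutation_rate=2.0,
            sweep=(sequence_length / 2, strength),
            seed=seed,
        )
    )
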