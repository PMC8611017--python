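"""Minimum-event copy-number phylogenies with ancestral reconstruction.

Distances between haplotype-specific integer copy-number profiles count the
minimum number of contiguous segmental +-1 events transforming one profile
into the other, with two biological constraints: events never span
chromosome boundaries, and a haplotype lost (copy number 0) can never be
regained — a transformation demanding a regain is infeasible.  The count is
computed per chromosome and haplotype by a scanline over the difference
signal (gains and losses are the sums of positive increments of their
respective difference signals, with zero-copy segments acting as event
barriers); an exhaustive breadth-first search over event sequences serves
as the independent oracle on small profiles.

Trees are built by neighbour joining on the symmetrised distance matrix
with an added all-ones diploid pseudo-sample as the root; ancestral
profiles are reconstructed per segment and haplotype with a Sankoff dynamic
programme under unit cost per copy-number step and an infeasibility bar on
0 -> positive transitions.  Branch support comes from jackknife resampling
of the joint segments.

This is a deliberate simplification of whole-genome-doubling-aware
minimum-evolution methods: no doubling events and no tree search beyond
neighbour joining.  The symmetrised distance does not satisfy the triangle
inequality (irreversible losses break it), which is why no such property is
asserted anywhere.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj

from .errors import InvalidInputError

ROOT_NAME = "diploid"


# ---------------------------------------------------------------------------
# minimum-event distance
# ---------------------------------------------------------------------------

def _scanline_events(diff: np.ndarray) -> int:
    """Events needed for one signed difference signal on one chromosome."""
    gains = np.maximum(diff, 0)
    losses = np.maximum(-diff, 0)
    n = 0
    for sig in (gains, losses):
        prev = 0
        for v in sig:
            if v > prev:
                n += v - prev
            prev = v
    return int(n)


def event_distance(a, b, chrom_index=None) -> float:
    """Directed minimum event count turning profile ``a`` into ``b``.

    ``a`` and ``b`` are equal-length integer vectors of one haplotype;
    ``chrom_index`` labels each segment's chromosome (events never span a
    boundary; a single chromosome is assumed when omitted).  Returns
    ``math.inf`` when any segment requires regaining a lost haplotype
    (a_i = 0 with b_i > 0).
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("profiles must be equal-length vectors")
    if np.any(a < 0) or np.any(b < 0):
        raise InvalidInputError("copy numbers must be >= 0")
    if np.any((a == 0) & (b > 0)):
        return math.inf
    if chrom_index is None:
        chrom_index = np.zeros(len(a), dtype=int)
    chrom_index = np.asarray(chrom_index)
    total = 0
    for c in pd.unique(chrom_index):
        sel = chrom_index == c
        total += _scanline_events(b[sel] - a[sel])
    return float(total)


def profile_distance(pa, pb, chrom_index=None) -> float:
    """Directed distance between two (segments x 2 haplotypes) profiles."""
    pa = np.asarray(pa, dtype=int)
    pb = np.asarray(pb, dtype=int)
    if pa.shape != pb.shape or pa.ndim != 2 or pa.shape[1] != 2:
        raise InvalidInputError("profiles must be (n_segments, 2) arrays")
    d = 0.0
    for h in (0, 1):
        d += event_distance(pa[:, h], pb[:, h], chrom_index)
        if math.isinf(d):
            return math.inf
    return d


def meet_ancestor_distance(pa, pb, chrom_index=None) -> float:
    """Finite distance for mutually infeasible pairs via a meet ancestor.

    Two profiles with complementary losses (each has a zero where the other
    is positive) are unreachable from one another in either direction; any
    valid history passes through a common ancestor carrying both alleles.
    The segment-wise meet — min(a, b) where both are positive, otherwise
    the non-zero value — is such an ancestor that retains every shared
    event, so the resulting d(meet -> a) + d(meet -> b) stays on the scale
    of the true path length and preserves shared-branch signal (an
    arbitrary large penalty would erase it and distort neighbour joining).
    """
    pa = np.asarray(pa, dtype=int)
    pb = np.asarray(pb, dtype=int)
    both_pos = (pa > 0) & (pb > 0)
    meet = np.where(both_pos, np.minimum(pa, pb), np.maximum(pa, pb))
    d = profile_distance(meet, pa, chrom_index) \
        + profile_distance(meet, pb, chrom_index)
    if math.isinf(d):   # cannot happen: meet is zero only where both are
        raise AssertionError("meet ancestor must reach both profiles")
    return d


def bfs_event_distances(a, chrom_index=None, max_cn: int | None = None) -> dict:
    """Exhaustive oracle: BFS over single-event moves from profile ``a``.

    Enumerates every haplotype vector reachable from ``a`` by contiguous
    +-1 events (within one chromosome, never touching zero-copy segments,
    capped at ``max_cn``) and returns ``{state_tuple: min_events}``.
    Unreached states are infeasible.  Exponential in the vector length —
    strictly a test oracle.
    """
    a = tuple(int(x) for x in a)
    if chrom_index is None:
        chrom_index = np.zeros(len(a), dtype=int)
    chrom_index = np.asarray(chrom_index)
    if max_cn is None:
        max_cn = max(a) + 2
    runs = []
    for c in pd.unique(chrom_index):
        idx = np.flatnonzero(chrom_index == c)
        for i in range(len(idx)):
            for j in range(i, len(idx)):
                runs.append(tuple(idx[i:j + 1]))
    dist = {a: 0}
    queue = deque([a])
    while queue:
        state = queue.popleft()
        d = dist[state]
        for run in runs:
            if any(state[i] == 0 for i in run):
                continue    # zero segments are barriers for both event types
            for delta in (1, -1):
                if delta == 1 and any(state[i] >= max_cn for i in run):
                    continue
                nxt = list(state)
                for i in run:
                    nxt[i] += delta
                nxt = tuple(nxt)
                if nxt not in dist:
                    dist[nxt] = d + 1
                    queue.append(nxt)
    return dist


# ---------------------------------------------------------------------------
# tree building
# ---------------------------------------------------------------------------

@dataclass
class CnTree:
    """NJ tree over samples rooted at an added diploid pseudo-sample."""

    tree: object                        # skbio TreeNode, root named 'diploid'
    distance_matrix: pd.DataFrame       # symmetrised
    directed: pd.DataFrame              # raw directed distances (inf allowed)
    infeasible_pairs: list = field(default_factory=list)
    ancestral: dict = field(default_factory=dict)     # node name -> profile
    branch_events: dict = field(default_factory=dict)  # node name -> events
    support: dict = field(default_factory=dict)       # frozenset -> percent

    def clades(self) -> set[frozenset]:
        return tree_clades(self.tree)

    def newick(self) -> str:
        s = str(self.tree).strip()
        return s


def tree_clades(tree, *, min_branch: float = 2.0) -> set[frozenset]:
    """Non-trivial rooted clades: sample-tip sets below internal nodes.

    Internal branches shorter than ``min_branch`` (default: two events) are
    treated as unresolved.  NJ always returns a binary tree, so a true
    multifurcation would otherwise appear as an arbitrary short resolution;
    and because parallel events hitting the same chromosome in independent
    lineages mimic up to ~1-2 events of shared signal, splits below that
    noise floor are not considered resolved.
    """
    tips = {t.name for t in tree.tips()} - {ROOT_NAME}
    out = set()
    for node in tree.non_tips(include_self=False):
        if node.length is not None and node.length < min_branch:
            continue
        clade = frozenset(t.name for t in node.tips()) - {ROOT_NAME}
        if 2 <= len(clade) < len(tips):
            out.add(clade)
    return out


def rooted_rf(clades_a: set, clades_b: set) -> int:
    """Robinson-Foulds distance between two rooted clade sets."""
    return len(clades_a ^ clades_b)


def _distance_matrices(profiles: dict, chrom_index):
    names = list(profiles)
    n_seg = next(iter(profiles.values())).shape[0]
    all_profiles = dict(profiles)
    all_profiles[ROOT_NAME] = np.ones((n_seg, 2), dtype=int)
    labels = names + [ROOT_NAME]
    k = len(labels)
    directed = np.zeros((k, k))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                directed[i, j] = profile_distance(all_profiles[a],
                                                  all_profiles[b], chrom_index)
    sym = np.minimum(directed, directed.T)
    infeasible = []
    for i in range(k):
        for j in range(i + 1, k):
            if math.isinf(sym[i, j]):
                infeasible.append((labels[i], labels[j]))
                sym[i, j] = sym[j, i] = meet_ancestor_distance(
                    all_profiles[labels[i]], all_profiles[labels[j]],
                    chrom_index)
    return (pd.DataFrame(sym, index=labels, columns=labels),
            pd.DataFrame(directed, index=labels, columns=labels),
            infeasible)


def build_cn_tree(profiles: dict, chrom_index=None) -> CnTree:
    """Neighbour-joining tree over haplotype-specific profiles.

    ``profiles`` maps sample name -> (n_segments, 2) integer array.  The
    distance is the symmetrised minimum-event distance (minimum of the two
    feasible directions; a mutually infeasible pair receives a large finite
    penalty and is flagged).  An all-ones diploid pseudo-sample roots the
    tree; negative NJ branch lengths are clamped to zero.
    """
    if len(profiles) < 2:
        raise InvalidInputError("need at least two samples")
    shapes = {p.shape for p in profiles.values()}
    if len(shapes) != 1:
        raise InvalidInputError("profiles disagree on segment count")
    sym, directed, infeasible = _distance_matrices(profiles, chrom_index)
    dm = DistanceMatrix(sym.to_numpy(), ids=list(sym.index))
    unrooted = nj(dm)
    tree = unrooted.root_at(unrooted.find(ROOT_NAME))
    tree.name = ROOT_NAME
    i = 0
    for node in tree.postorder():
        if node.length is not None and node.length < 0:
            node.length = 0.0
        if not node.is_tip() and node.name is None:
            i += 1
            node.name = f"anc{i}"
    return CnTree(tree=tree, distance_matrix=sym, directed=directed,
                  infeasible_pairs=infeasible)


# ---------------------------------------------------------------------------
# ancestral reconstruction
# ---------------------------------------------------------------------------

def reconstruct_ancestors(cn_tree: CnTree, profiles: dict,
                          chrom_index=None) -> CnTree:
    """Sankoff reconstruction of internal haplotype profiles.

    Per segment and haplotype, a dynamic programme over integer states with
    cost |s - t| per branch and an infinite cost on 0 -> positive
    transitions; the root is fixed to the diploid state.  Ties break toward
    the smaller copy number.  Branch event counts are then recomputed with
    the contiguity-aware :func:`event_distance` from parent to child.
    """
    n_seg = next(iter(profiles.values())).shape[0]
    max_cn = max(int(p.max()) for p in profiles.values()) + 2
    states = np.arange(max_cn + 1)
    step = np.abs(states[:, None] - states[None, :]).astype(float)
    step[0, 1:] = math.inf    # lost alleles are never regained

    tree = cn_tree.tree
    nodes = list(tree.postorder())
    node_profiles = {n.name: np.zeros((n_seg, 2), dtype=int) for n in nodes
                     if not n.is_tip()}
    node_profiles[ROOT_NAME] = np.ones((n_seg, 2), dtype=int)
    infeasible_segments = []

    for seg in range(n_seg):
        for hap in (0, 1):
            cost = {}
            for node in nodes:
                if node.is_tip():
                    obs = int(profiles[node.name][seg, hap])
                    c = np.full(len(states), math.inf)
                    if obs <= max_cn:
                        c[obs] = 0.0
                    cost[node.name] = c
                else:
                    c = np.zeros(len(states))
                    for child in node.children:
                        c = c + np.min(step + cost[child.name][None, :],
                                       axis=1)
                    cost[node.name] = c
            if not math.isfinite(cost[ROOT_NAME][1]):
                infeasible_segments.append((seg, hap))
                continue
            # top-down assignment, root fixed diploid
            assign = {ROOT_NAME: 1}
            for node in tree.preorder(include_self=True):
                if node.name == ROOT_NAME:
                    s = 1
                else:
                    s = assign[node.name]
                for child in node.children:
                    totals = step[s] + cost[child.name]
                    t = int(np.argmin(totals))   # argmin takes smallest state
                    assign[child.name] = t
                    if not child.is_tip():
                        node_profiles[child.name][seg, hap] = t
    if infeasible_segments:
        raise InvalidInputError(
            "no feasible ancestral labelling (a child would require "
            f"regaining a lost allele) at (segment, haplotype): "
            f"{infeasible_segments}")

    all_profiles = dict(profiles)
    all_profiles.update(node_profiles)
    branch_events = {}
    for node in tree.preorder(include_self=False):
        branch_events[node.name] = profile_distance(
            all_profiles[node.parent.name], all_profiles[node.name],
            chrom_index)
    cn_tree.ancestral = node_profiles
    cn_tree.branch_events = branch_events
    return cn_tree


# ---------------------------------------------------------------------------
# jackknife support
# ---------------------------------------------------------------------------

def jackknife_support(profiles: dict, chrom_index=None, *,
                      n_replicates: int = 100, drop_fraction: float = 0.5,
                      seed=0) -> dict:
    """Per-clade support from jackknife resampling of joint segments.

    Each replicate drops ``drop_fraction`` of the segments uniformly without
    replacement, rebuilds the NJ tree and scores every clade of the original
    tree by the percentage of replicates containing it.  Deterministic given
    the seed.
    """
    if not 0.0 < drop_fraction < 1.0:
        raise InvalidInputError("drop_fraction must lie in (0, 1)")
    if len(profiles) < 3:
        raise InvalidInputError("jackknife support needs >= 3 samples")
    n_seg = next(iter(profiles.values())).shape[0]
    if chrom_index is None:
        chrom_index = np.zeros(n_seg, dtype=int)
    chrom_index = np.asarray(chrom_index)
    base = build_cn_tree(profiles, chrom_index)
    targets = base.clades()
    counts = {c: 0 for c in targets}
    rng = np.random.default_rng(seed)
    n_keep = max(1, n_seg - int(round(drop_fraction * n_seg)))
    for _ in range(n_replicates):
        keep = np.sort(rng.choice(n_seg, size=n_keep, replace=False))
        sub = {k: v[keep] for k, v in profiles.items()}
        rep = build_cn_tree(sub, chrom_index[keep])
        # containment in a replicate is a topology question: the resolution
        # filter stays off, otherwise dropping half the supporting segments
        # would count as disagreement even when the split is reproduced
        rep_clades = tree_clades(rep.tree, min_branch=1e-9)
        for c in targets:
            if c in rep_clades:
                counts[c] += 1
    return {c: 100.0 * counts[c] / n_replicates for c in targets}
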