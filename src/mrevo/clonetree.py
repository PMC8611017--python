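"""Clone-tree reconstruction from VAF clusters.

Clusters of somatic SNVs with per-sample cellular fractions (CF) are turned
into a rooted clone tree with explicit rules:

* clusters with CF > 90% in every sample merge into the founding clone
  (the trunk);
* the remaining clusters are grouped by their sample-presence pattern
  (CF >= 5%), and each clone's parent must be present in the same and
  potentially more samples;
* clusters present in a single sample become leaves;
* branch lengths are SNV counts.

Clusters sharing one presence pattern stay distinct clones chained in order
of decreasing mean CF.  Parent ties between different patterns of equal
size are broken by larger mean CF, then by cluster id, so reconstruction is
deterministic.  Clusters admitting no superset parent attach to the trunk
with an ``unplaced`` flag instead of failing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, InvalidTreeError, OrphanRootError

FOUNDING_CF = 0.90
PRESENCE_CF = 0.05
MIN_INFORMATIVE_SNVS = 5


@dataclass
class VafCluster:
    """One SNV cluster: per-sample cellular fraction plus its member SNVs."""

    id: int
    cf: np.ndarray
    n_snvs: int
    snv_ids: tuple = ()

    def __post_init__(self) -> None:
        self.cf = np.asarray(self.cf, dtype=float)
        if self.n_snvs < 0:
            raise InvalidInputError("n_snvs must be >= 0")


@dataclass
class Clone:
    id: int
    cluster_ids: list[int]
    cf: np.ndarray              # per-sample cellular fraction
    n_snvs: int                 # branch length
    parent: int | None          # clone id of the parent; None for the trunk
    presence: frozenset         # sample indices with CF >= presence threshold
    snv_ids: tuple = ()
    flags: list[str] = field(default_factory=list)

    @property
    def mean_cf(self) -> float:
        return float(self.cf.mean())


@dataclass
class CloneTreeResult:
    clones: list[Clone]                     # clones[0] is the founding clone
    sample_ids: list[str]
    presence_threshold: float
    sample_annotation: dict = field(default_factory=dict)
    intermixed_samples: set = field(default_factory=set)
    warnings: list[str] = field(default_factory=list)

    @property
    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {c.id: [] for c in self.clones}
        for c in self.clones:
            if c.parent is not None:
                ch[c.parent].append(c.id)
        return ch

    def clone(self, clone_id: int) -> Clone:
        return self.clones[clone_id]

    def depth(self, clone_id: int) -> int:
        d, c = 0, self.clones[clone_id]
        while c.parent is not None:
            d, c = d + 1, self.clones[c.parent]
        return d

    def is_ancestor(self, a: int, b: int) -> bool:
        while b is not None:
            if b == a:
                return True
            b = self.clones[b].parent
        return False


@dataclass
class InsufficientSignal:
    """Returned when too few informative SNVs exist to infer a tree."""

    n_informative: int
    threshold: int
    reason: str = "too few SNVs with non-zero median VAF"


def build_clone_tree(clusters, *, founding_threshold: float = FOUNDING_CF,
                     presence_threshold: float = PRESENCE_CF,
                     sample_ids=None) -> CloneTreeResult:
    """Assemble the clone tree from VAF clusters by the presence-pattern rules."""
    if not clusters:
        raise InvalidInputError("at least one cluster is required")
    n_samples = clusters[0].cf.size
    if sample_ids is None:
        sample_ids = [f"S{j + 1:02d}" for j in range(n_samples)]
    for c in clusters:
        if c.cf.size != n_samples:
            raise InvalidInputError("clusters disagree on the sample count")

    founding = [c for c in clusters if np.all(c.cf > founding_threshold)]
    rest = [c for c in clusters if not np.all(c.cf > founding_threshold)]
    if not founding:
        raise OrphanRootError(
            "no cluster has CF > {:.0%} in all samples; no founding clone "
            "can be formed — review purity estimates or the founding "
            "threshold".format(founding_threshold))

    w = np.array([max(c.n_snvs, 1) for c in founding], dtype=float)
    trunk_cf = np.average(np.stack([c.cf for c in founding]), axis=0, weights=w)
    trunk = Clone(id=0,
                  cluster_ids=[c.id for c in founding],
                  cf=trunk_cf,
                  n_snvs=sum(c.n_snvs for c in founding),
                  parent=None,
                  presence=frozenset(range(n_samples)),
                  snv_ids=tuple(s for c in founding for s in c.snv_ids))
    clones = [trunk]

    def pres(c: VafCluster) -> frozenset:
        return frozenset(int(j) for j in np.flatnonzero(c.cf >= presence_threshold))

    order = sorted(rest, key=lambda c: (-len(pres(c)), -float(c.cf.mean()), c.id))
    for c in order:
        p = pres(c)
        clone = Clone(id=len(clones), cluster_ids=[c.id], cf=c.cf.copy(),
                      n_snvs=c.n_snvs, parent=None, presence=p,
                      snv_ids=tuple(c.snv_ids))
        if not p:
            clone.parent = 0
            clone.flags.append("unplaced")
            clones.append(clone)
            continue
        candidates = [q for q in clones if p <= q.presence]
        if not candidates:
            clone.parent = 0
            clone.flags.append("unplaced")
            clones.append(clone)
            continue
        # the parent must be able to contain the child: CF-dominance in the
        # child's samples (with tolerance); ignored if it empties the pool
        dominating = [q for q in candidates
                      if all(q.cf[s] >= clone.cf[s] - 0.05 for s in p)]
        pool0 = dominating or candidates
        same = [q for q in pool0 if q.presence == p]
        if same:
            # chain same-pattern clones in decreasing-CF order
            clone.parent = min(same, key=lambda q: (q.mean_cf, -q.id)).id
        else:
            # clones sharing a presence pattern form a chain; only the
            # deepest (lowest-CF) member is a valid attachment point —
            # its ancestors are interior to the chain
            reps: dict = {}
            for q in pool0:
                r = reps.get(q.presence)
                if r is None or (q.mean_cf, -q.id) < (r.mean_cf, -r.id):
                    reps[q.presence] = q
            size = min(len(pat) for pat in reps)
            pool = [q for pat, q in reps.items() if len(pat) == size]
            clone.parent = max(pool, key=lambda q: (q.mean_cf, -q.id)).id
        clones.append(clone)

    result = CloneTreeResult(clones=clones, sample_ids=list(sample_ids),
                             presence_threshold=presence_threshold)
    result.warnings.extend(check_sibling_cf(result))
    annotate_samples(result)
    return result


def check_sibling_cf(result: CloneTreeResult, tol: float = 0.05) -> list[str]:
    """Report (never silently fix) samples where sibling CFs overflow the parent."""
    msgs = []
    for pid, kids in result.children.items():
        if not kids:
            continue
        parent_cf = result.clones[pid].cf
        sib_sum = np.sum([result.clones[k].cf for k in kids], axis=0)
        for s in np.flatnonzero(sib_sum > parent_cf + tol):
            msgs.append(
                f"sample {result.sample_ids[s]}: children of clone {pid} sum "
                f"to CF {sib_sum[s]:.3f} > parent {parent_cf[s]:.3f} + {tol}")
    return msgs


def annotate_samples(result: CloneTreeResult) -> dict:
    """Annotate each sample at its deepest contained clone.

    The annotation clone is the one furthest from the tree stem among clones
    with CF >= the presence threshold in that sample.  Samples carrying
    clones from more than one branch (two present clones, neither ancestral
    to the other) are flagged as clonally intermixed.
    """
    thr = result.presence_threshold
    annotation: dict = {}
    intermixed: set = set()
    for s, sid in enumerate(result.sample_ids):
        present = [c.id for c in result.clones if c.cf[s] >= thr]
        if not present:
            present = [0]
        deepest = max(present,
                      key=lambda cid: (result.depth(cid),
                                       result.clones[cid].cf[s], -cid))
        annotation[sid] = deepest
        for a in present:
            for b in present:
                if a < b and not (result.is_ancestor(a, b)
                                  or result.is_ancestor(b, a)):
                    intermixed.add(sid)
    result.sample_annotation = annotation
    result.intermixed_samples = intermixed
    return annotation


def recovered_parent_vector(result: CloneTreeResult,
                            n_clusters: int) -> np.ndarray | None:
    """Map the reconstructed tree back to a cluster-indexed parent vector.

    Usable only when cluster ids are 0..n-1, cluster 0 is the sole trunk
    member and every other cluster forms its own clone; returns None
    otherwise (e.g. when extra clusters were merged into the trunk).
    """
    by_cluster: dict[int, Clone] = {}
    for clone in result.clones:
        for cid in clone.cluster_ids:
            by_cluster[cid] = clone
    if set(by_cluster) != set(range(n_clusters)):
        return None
    if result.clones[0].cluster_ids != [0]:
        return None
    parent = np.full(n_clusters, -1, dtype=int)
    for cid in range(1, n_clusters):
        clone = by_cluster[cid]
        if clone.cluster_ids != [cid] or clone.parent is None:
            return None
        pclone = result.clones[clone.parent]
        if len(pclone.cluster_ids) != 1:
            return None
        parent[cid] = pclone.cluster_ids[0]
    return parent


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def tree_to_newick(result: CloneTreeResult) -> str:
    """Newick string with clone labels and SNV-count branch lengths."""
    children = result.children

    def rec(cid: int) -> str:
        c = result.clones[cid]
        label = f"c{cid}:{c.n_snvs}"
        kids = children[cid]
        if not kids:
            return label
        return "(" + ",".join(rec(k) for k in kids) + ")" + label

    return rec(0) + ";"


_TOKEN = re.compile(r"\(|\)|,|;|[^(),;:]+(?::[0-9.]+)?")


def parse_newick(text: str) -> dict[str, tuple[str | None, float]]:
    """Parse a Newick string into ``{label: (parent_label, branch_length)}``.

    Supports the subset emitted by :func:`tree_to_newick`; raises on
    malformed input.  Used for round-trip checks of the export.
    """
    tokens = _TOKEN.findall(text.strip())
    if not tokens or tokens[-1] != ";":
        raise InvalidInputError("newick string must end with ';'")
    out: dict[str, tuple[str | None, float]] = {}
    stack: list[list[str]] = []
    pending: list[str] = []

    def close(label_token: str, children: list[str]) -> str:
        if ":" in label_token:
            name, ln = label_token.rsplit(":", 1)
            length = float(ln)
        else:
            name, length = label_token, 0.0
        if not name:
            raise InvalidInputError("unnamed internal node")
        out[name] = (None, length)
        for ch in children:
            out[ch] = (name, out[ch][1])
        return name

    i = 0
    while i < len(tokens):
        t = tokens[i]
        if t == "(":
            stack.append(pending)
            pending = []
        elif t == ",":
            pass
        elif t == ")":
            i += 1
            label = tokens[i]
            node = close(label, pending)
            pending = stack.pop()
            pending.append(node)
        elif t == ";":
            break
        else:
            node = close(t, [])
            pending.append(node)
        i += 1
    if len(pending) != 1 or stack:
        raise InvalidInputError("malformed newick string")
    return out


def edge_list(result: CloneTreeResult) -> pd.DataFrame:
    rows = [(c.parent, c.id, c.n_snvs,
             ";".join(sorted(f))) for c in result.clones
            for f in [c.flags] if c.parent is not None]
    return pd.DataFrame(rows, columns=["parent", "child", "n_snvs", "flags"])


def tree_to_dot(result: CloneTreeResult) -> str:
    """Graphviz DOT export for quick plotting."""
    lines = ["digraph clones {", "  node [shape=circle];"]
    for c in result.clones:
        lines.append(f'  c{c.id} [label="c{c.id}\\n{c.n_snvs} SNVs"];')
    for c in result.clones:
        if c.parent is not None:
            lines.append(f"  c{c.parent} -> c{c.id};")
    for sid, cid in result.sample_annotation.items():
        lines.append(f'  "{sid}" [shape=box];')
        lines.append(f'  c{cid} -> "{sid}" [style=dashed];')
    lines.append("}")
    return "\n".join(lines)


def validate_tree(result: CloneTreeResult) -> list[str]:
    """Assert structural invariants; returns the list of soft warnings.

    Hard invariants (raise): acyclic parent mapping and, along any
    root-to-leaf path, nested presence sets for clones not flagged
    'unplaced'.  Soft ones (returned): sibling CF sums.
    """
    seen_root = False
    for c in result.clones:
        visited = set()
        node = c.id
        while node is not None:
            if node in visited:
                raise InvalidTreeError(f"cycle through clone {node}")
            visited.add(node)
            node = result.clones[node].parent
        if c.parent is None:
            if seen_root:
                raise InvalidTreeError("multiple roots")
            seen_root = True
        elif "unplaced" not in c.flags:
            if not c.presence <= result.clones[c.parent].presence:
                raise InvalidTreeError(
                    f"presence of clone {c.id} is not nested in its parent")
    return check_sibling_cf(result)
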