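"""Distance phylogenetics for marker-gene clone sequences.

Builds neighbor-joining trees from Jukes-Cantor distances with bootstrap
supports, the standard recipe for placing clone-library sequences: the JC69
model assumes equal base frequencies and a single substitution rate, and
corrects the observed proportion of differing sites p by
d = -(3/4) ln(1 - 4p/3). Gapped positions are removed pairwise, not
alignment-wide. Negative branch-length estimates are clamped to zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skbio import DistanceMatrix, TreeNode


class SaturationError(ValueError):
    """p >= 0.75: beyond the Jukes-Cantor correction's domain."""

    def __init__(self, p: float, pair=("a", "b")):
        self.p = p
        self.pair = pair
        super().__init__(f"sequences {pair[0]!r} and {pair[1]!r} are saturated "
                         f"(p = {p:.4f} >= 0.75); JC distance undefined")


@dataclass
class AlignedSet:
    """A multiple alignment: parallel ids and equal-length gapped rows."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"rows are not aligned (lengths {sorted(lengths)})")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @classmethod
    def from_fasta(cls, path) -> "AlignedSet":
        from Bio import SeqIO
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids, rows)

    def resample_columns(self, rng: np.random.Generator) -> "AlignedSet":
        cols = rng.integers(0, self.length, size=self.length)
        return AlignedSet(list(self.ids),
                          ["".join(r[c] for c in cols) for r in self.rows])


def jc_distance(a: str, b: str, ids=("a", "b")) -> float:
    """Jukes-Cantor distance with pairwise gap deletion."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    comparable = 0
    mismatches = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-." or y in "-.":
            continue
        comparable += 1
        if x != y:
            mismatches += 1
    if comparable == 0:
        raise ValueError(f"no comparable (both non-gap) sites between "
                         f"{ids[0]!r} and {ids[1]!r}")
    p = mismatches / comparable
    return jc_from_p(p, ids)


def jc_from_p(p: float, ids=("a", "b")) -> float:
    """d = -(3/4) ln(1 - 4p/3); raises SaturationError for p >= 3/4."""
    if p >= 0.75:
        raise SaturationError(p, ids)
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_matrix(aln: AlignedSet) -> DistanceMatrix:
    n = len(aln.ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jc_distance(aln.rows[i], aln.rows[j],
                                            (aln.ids[i], aln.ids[j]))
    return DistanceMatrix(d, ids=aln.ids)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; returns an unrooted (trifurcating) tree.

    At each step the pair minimizing Q(i,j) = (n-2) d(i,j) - r_i - r_j is
    agglomerated (ties broken by the smallest index pair, so the result is
    deterministic); branch lengths follow the standard split formula with
    negative estimates clamped to zero. Accepts a skbio DistanceMatrix or a
    plain square array (taxa then named by index).
    """
    if not isinstance(dm, DistanceMatrix):
        arr = np.asarray(dm, dtype=float)
        if not np.allclose(arr, arr.T):
            raise ValueError("distance matrix must be symmetric")
        dm = DistanceMatrix(arr, ids=[str(i) for i in range(arr.shape[0])])
    d = np.array(dm.data, dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(name=str(i)) for i in dm.ids]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # smallest Q; ties -> smallest (i, j) index pair in current ordering
        flat = np.argmin(q)
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        li = 0.5 * sub[ai, aj] + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = sub[ai, aj] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        # distances from the new node u to every other active node k
        new_row = 0.5 * (d[i, active] + d[j, active] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        u = d.shape[0] - 1
        d[u, active] = new_row
        d[active, u] = new_row
        d[u, u] = 0.0
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]
    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    root = TreeNode()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        nodes[k].length = max(lk, 0.0)
        root.append(nodes[k])
    return root


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of the smaller-side leaf names."""
    leaves = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(leaves) - 1:
            other = leaves - side
            out.add(side if (len(side), sorted(side)) <= (len(other), sorted(other))
                    else other)
    return out


def bootstrap_support(aln: AlignedSet, n_reps: int = 1000, seed: int = 0,
                      max_skip_frac: float = 0.05) -> TreeNode:
    """NJ tree from the full alignment with bootstrap supports.

    Alignment columns are resampled with replacement ``n_reps`` times; each
    replicate tree is rebuilt via JC distances + neighbor joining, and each
    internal edge of the full-data tree is annotated (node name) with the
    percentage of replicates containing the same leaf bipartition.
    Replicates with a saturated pair or no comparable sites are skipped and
    counted; a warning is emitted if more than ``max_skip_frac`` are lost.
    """
    if aln.length < 1:
        raise ValueError("alignment must have at least 1 column")
    if len(aln.ids) < 3:
        raise ValueError("need at least 3 sequences")
    tree = neighbor_joining(jc_matrix(aln))
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in _bipartitions(tree)}
    skipped = 0
    for _ in range(n_reps):
        rep = aln.resample_columns(rng)
        try:
            rep_bps = _bipartitions(neighbor_joining(jc_matrix(rep)))
        except (SaturationError, ValueError):
            skipped += 1
            continue
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    used = n_reps - skipped
    if skipped > max_skip_frac * n_reps:
        warnings.warn(f"{skipped}/{n_reps} bootstrap replicates skipped "
                      "(saturated distances)", stacklevel=2)
    leaves = frozenset(t.name for t in tree.tips())
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        key = side if (len(side), sorted(side)) <= (len(other), sorted(other)) else other
        if key in counts and used > 0:
            node.name = str(round(100 * counts[key] / used))
    return tree


def root_at_outgroup(tree: TreeNode, outgroup: str) -> TreeNode:
    """Re-root the unrooted NJ tree on the named outgroup leaf."""
    target = tree.find(outgroup)
    return tree.root_at(target.parent) if target.parent is not None else tree


def to_newick(tree: TreeNode) -> str:
    import io
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()
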