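"""Distance-based phylogenetics: progressive multiple alignment,
p/Poisson distances, neighbor-joining with bootstrap supports, and
reference-guided subfamily assignment.

Neighbor-joining follows Saitou & Nei's Q-criterion agglomeration with
MEGA-style clamping of negative branch lengths to zero.  Ties in the
Q matrix are broken toward the lowest (row, column) index pair in the
current node order, which together with a fixed seed stream makes trees
reproducible bit for bit.

The progressive aligner replaces an external MSA program: guide order
comes from a k-mer-distance NJ tree and profiles are merged by global
affine-gap alignment under BLOSUM62.  It is adequate at the desk scale
this package targets and keeps the pipeline free of external binaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from Bio.Align import substitution_matrices

from .exceptions import FamSurveyError, UndefinedDistanceError
from .io import AMINO_ACIDS

GAP = "-"


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class PhyloTree:
    """Unrooted tree held in a rooted representation (root = final join).

    ``supports`` maps canonical internal bipartitions (leaf frozensets) to
    bootstrap percentages in [0, 100].
    """

    root: TreeNode
    supports: dict[frozenset, float] | None = None

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node.name)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def _canonical(self, leafset: frozenset) -> frozenset:
        all_leaves = frozenset(self.leaves())
        anchor = min(all_leaves)
        return all_leaves - leafset if anchor in leafset else leafset

    def bipartitions(self) -> set[frozenset]:
        """Canonical leaf sets of all internal (non-pendant) edges."""
        result: set[frozenset] = set()

        def walk(node: TreeNode) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                below |= walk(child)
            if node is not self.root:
                result.add(self._canonical(below))
            return below

        walk(self.root)
        return result

    def path_length_matrix(self) -> tuple[list[str], np.ndarray]:
        """Leaf-to-leaf path lengths (sums of branch lengths)."""
        adjacency: dict[int, list[tuple[int, float]]] = {}
        names: dict[int, str] = {}
        counter = [0]

        def index(node: TreeNode) -> int:
            counter[0] += 1
            return counter[0] - 1

        def walk(node: TreeNode, idx: int) -> None:
            if node.is_leaf:
                names[idx] = node.name
            for child, length in node.children:
                cidx = index(child)
                adjacency.setdefault(idx, []).append((cidx, length))
                adjacency.setdefault(cidx, []).append((idx, length))
                walk(child, cidx)

        root_idx = index(self.root)
        walk(self.root, root_idx)

        labels = sorted(names.values())
        pos = {name: i for i, name in enumerate(labels)}
        n = len(labels)
        dist = np.zeros((n, n))
        for idx, name in names.items():
            # BFS over the tree (acyclic): accumulate path lengths
            seen = {idx: 0.0}
            stack = [idx]
            while stack:
                cur = stack.pop()
                for nxt, length in adjacency.get(cur, []):
                    if nxt not in seen:
                        seen[nxt] = seen[cur] + length
                        stack.append(nxt)
            for other_idx, other_name in names.items():
                dist[pos[name], pos[other_name]] = seen[other_idx]
        return labels, dist

    def to_newick(self, with_supports: bool = False, decimals: int = 6) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            parts = []
            for child, length in node.children:
                label = ""
                if with_supports and self.supports and not child.is_leaf:
                    leafset = frozenset(_leaves_under(child))
                    support = self.supports.get(self._canonical(leafset))
                    if support is not None:
                        label = str(int(round(support)))
                parts.append(f"{fmt(child)}{label}:{length:.{decimals}f}")
            return "(" + ",".join(parts) + ")"

        return fmt(self.root) + ";"


def _leaves_under(node: TreeNode) -> list[str]:
    if node.is_leaf:
        return [node.name]
    out: list[str] = []
    for child, _ in node.children:
        out.extend(_leaves_under(child))
    return out


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix has nonzero diagonal")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix has non-finite entries")


_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def _encode_alignment(alignment: Mapping[str, str]) -> tuple[list[str], np.ndarray]:
    labels = list(alignment)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("alignment rows have unequal lengths")
    rows = np.array([
        [(_AA_INDEX.get(c, 20) if c != GAP else -1) for c in alignment[label]]
        for label in labels
    ], dtype=np.int16)
    return labels, rows


def distance_matrix(alignment: Mapping[str, str],
                    model: str = "p-distance") -> DistanceMatrix:
    """Pairwise distances over shared ungapped sites.

    ``p-distance``: mismatches / valid sites.  ``poisson``: -ln(1 - p).
    A pair with no shared ungapped site raises
    :class:`UndefinedDistanceError` naming the pair.
    """
    if len(alignment) < 2:
        raise FamSurveyError("distance_matrix needs at least 2 rows")
    labels, rows = _encode_alignment(alignment)
    valid = (rows[:, None, :] >= 0) & (rows[None, :, :] >= 0)
    diff = (rows[:, None, :] != rows[None, :, :]) & valid
    n_valid = valid.sum(axis=2)
    undefined = (n_valid == 0) & ~np.eye(len(labels), dtype=bool)
    if undefined.any():
        i, j = np.argwhere(undefined)[0]
        raise UndefinedDistanceError(
            f"no shared ungapped sites between {labels[i]} and {labels[j]}"
        )
    with np.errstate(invalid="ignore"):
        p = diff.sum(axis=2) / np.maximum(n_valid, 1)
    if model in ("p", "p-distance"):
        d = p
    elif model == "poisson":
        if np.any(p >= 1.0):
            i, j = np.argwhere(p >= 1.0)[0]
            raise UndefinedDistanceError(
                f"Poisson distance undefined (p=1) between {labels[i]} and {labels[j]}"
            )
        d = -np.log1p(-p)
    else:
        raise ValueError(f"unknown distance model {model!r}")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# Neighbor-joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor-joining; needs at least 3 labels.

    Negative branch lengths are clamped to zero.  Q-matrix ties break
    toward the lowest (i, j) pair in the current node order, so output is
    deterministic and independent of input label order up to isomorphism.
    """
    n = len(dm.labels)
    if n < 3:
        raise FamSurveyError("neighbor_joining requires at least 3 labels")
    D = dm.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=label) for label in dm.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # np.argmin is row-major: first minimum = lowest (i, j) pair
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_dist = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.zeros((len(keep) + 1, len(keep) + 1))
        D_new[:-1, :-1] = D[np.ix_(keep, keep)]
        D_new[-1, :-1] = new_dist[keep]
        D_new[:-1, -1] = new_dist[keep]
        nodes = [nodes[k] for k in keep] + [parent]
        D = D_new

    # resolve the final three nodes around a central (unrooted) vertex
    a, b, c = 0, 1, 2
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    root = TreeNode(children=[
        (nodes[a], max(la, 0.0)),
        (nodes[b], max(lb, 0.0)),
        (nodes[c], max(lc, 0.0)),
    ])
    return PhyloTree(root=root)


def bootstrap_supports(alignment: Mapping[str, str], n_replicates: int,
                       seed: int, model: str = "p-distance",
                       max_redraw_factor: int = 10,
                       ) -> PhyloTree:
    """Column-resampling bootstrap supports on the full-data NJ tree.

    Rows are processed in sorted label order, so supports are invariant to
    the input leaf order under the same seed.  A replicate whose resampled
    columns leave some pairwise distance undefined is redrawn, up to
    ``max_redraw_factor * n_replicates`` draws in total.
    """
    if n_replicates < 1:
        raise FamSurveyError("n_replicates must be >= 1")
    ordered = {k: alignment[k] for k in sorted(alignment)}
    full_tree = neighbor_joining(distance_matrix(ordered, model))
    targets = full_tree.bipartitions()
    counts = {bp: 0 for bp in targets}

    labels, rows = _encode_alignment(ordered)
    n_cols = rows.shape[1]
    rng = np.random.default_rng(seed)
    done = 0
    draws = 0
    budget = max_redraw_factor * n_replicates
    while done < n_replicates:
        if draws >= budget:
            raise UndefinedDistanceError(
                "bootstrap redraw budget exhausted (too many gap-only replicates)"
            )
        draws += 1
        cols = rng.integers(0, n_cols, size=n_cols)
        replicate = {
            label: "".join(ordered[label][c] for c in cols) for label in labels
        }
        try:
            tree = neighbor_joining(distance_matrix(replicate, model))
        except UndefinedDistanceError:
            continue
        rep_bps = tree.bipartitions()
        for bp in targets:
            if bp in rep_bps:
                counts[bp] += 1
        done += 1

    full_tree.supports = {
        bp: 100.0 * c / n_replicates for bp, c in counts.items()
    }
    return full_tree


def assign_subfamilies(tree: PhyloTree,
                       reference_labels: Mapping[str, str]) -> dict[str, str]:
    """Label every leaf with the subfamily of its nearest reference leaf.

    Nearness is tree path length; exact ties break toward the subfamily
    with more reference leaves, then lexicographically.
    """
    if not reference_labels:
        raise FamSurveyError("assign_subfamilies needs at least one reference leaf")
    labels, dist = tree.path_length_matrix()
    pos = {name: i for i, name in enumerate(labels)}
    ref_sizes: dict[str, int] = {}
    for subfam in reference_labels.values():
        ref_sizes[subfam] = ref_sizes.get(subfam, 0) + 1

    result: dict[str, str] = {}
    for leaf in labels:
        if leaf in reference_labels:
            result[leaf] = reference_labels[leaf]
            continue
        best: tuple[float, int, str] | None = None
        for ref, subfam in reference_labels.items():
            if ref not in pos:
                raise FamSurveyError(f"reference leaf {ref} not in tree")
            key = (dist[pos[leaf], pos[ref]], -ref_sizes[subfam], subfam)
            if best is None or key < best:
                best = key
        result[leaf] = best[2]
    return result


# ---------------------------------------------------------------------------
# Progressive multiple alignment
# ---------------------------------------------------------------------------

def _blosum_matrix(name: str = "BLOSUM62") -> np.ndarray:
    mat = substitution_matrices.load(name)
    out = np.zeros((21, 21))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = mat[a][b]
    # index 20 = unknown residue (X): score 0 against everything
    return out


def _profile_frequencies(rows: list[str]) -> np.ndarray:
    """Residue frequency per column (gaps dilute; they carry no score)."""
    length = len(rows[0])
    freq = np.zeros((length, 21))
    for row in rows:
        for i, c in enumerate(row):
            if c != GAP:
                freq[i, _AA_INDEX.get(c, 20)] += 1
    return freq / len(rows)


def _align_profiles(rows_a: list[str], rows_b: list[str],
                    subst: np.ndarray, gap_open: float, gap_extend: float,
                    ) -> tuple[list[str], list[str]]:
    """Global affine-gap (Gotoh) alignment of two profiles.

    A gap of length L costs gap_open + L * gap_extend.
    """
    fa = _profile_frequencies(rows_a)
    fb = _profile_frequencies(rows_b)
    S = fa @ subst @ fb.T
    la, lb = S.shape
    NEG = -1e30
    open_cost = gap_open + gap_extend

    M = np.full((la + 1, lb + 1), NEG)
    Ix = np.full((la + 1, lb + 1), NEG)  # gap in profile B (consume A)
    Iy = np.full((la + 1, lb + 1), NEG)  # gap in profile A (consume B)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        Ix[i, 0] = -(gap_open + i * gap_extend)
    for j in range(1, lb + 1):
        Iy[0, j] = -(gap_open + j * gap_extend)

    # three-state DP; pure-Python loops are acceptable at desk scale
    for i in range(1, la + 1):
        Mi, Mi1 = M[i], M[i - 1]
        Ixi, Ixi1 = Ix[i], Ix[i - 1]
        Iyi = Iy[i]
        Si = S[i - 1]
        for j in range(1, lb + 1):
            best_prev = max(Mi1[j - 1], Ixi1[j - 1], Iy[i - 1][j - 1])
            Mi[j] = best_prev + Si[j - 1]
            Ixi[j] = max(Mi1[j] - open_cost, Ixi1[j] - gap_extend,
                         Iy[i - 1][j] - open_cost)
            Iyi[j] = max(Mi[j - 1] - open_cost, Iyi[j - 1] - gap_extend,
                         Ixi[j - 1] - open_cost)

    # traceback
    i, j = la, lb
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            ops.append("M")
            prev = [M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif (state == 1 and i > 0) or (j == 0 and i > 0):
            ops.append("X")
            cand = [M[i - 1][j] - open_cost, Ix[i - 1][j] - gap_extend,
                    Iy[i - 1][j] - open_cost]
            i -= 1
            state = int(np.argmax(cand)) if i > 0 or j > 0 else 0
        else:
            ops.append("Y")
            # candidate order must mirror the state codes (M, Ix, Iy)
            cand = [M[i][j - 1] - open_cost, Ix[i][j - 1] - open_cost,
                    Iy[i][j - 1] - gap_extend]
            j -= 1
            state = int(np.argmax(cand)) if i > 0 or j > 0 else 0
    ops.reverse()

    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ai = bi = 0
    for op in ops:
        if op in ("M", "X"):
            for k, row in enumerate(rows_a):
                out_a[k].append(row[ai])
            ai += 1
        else:
            for k in range(len(rows_a)):
                out_a[k].append(GAP)
        if op in ("M", "Y"):
            for k, row in enumerate(rows_b):
                out_b[k].append(row[bi])
            bi += 1
        else:
            for k in range(len(rows_b)):
                out_b[k].append(GAP)
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    from collections import Counter
    ca = Counter(a[i:i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i:i + k] for i in range(len(b) - k + 1))
    shared = sum(min(ca[w], cb[w]) for w in ca)
    return 1.0 - shared / min(sum(ca.values()), sum(cb.values()))


def progressive_msa(seqs: Mapping[str, str],
                    matrix: str | np.ndarray = "BLOSUM62",
                    gap_open: float = 11.0, gap_extend: float = 1.0,
                    guide_kmer: int = 3) -> dict[str, str]:
    """Progressive multiple alignment along a k-mer-distance NJ guide tree.

    Rows have equal length; removing gaps restores every input sequence.
    A single input sequence is returned unchanged.
    """
    labels = list(seqs)
    if not labels:
        raise FamSurveyError("progressive_msa needs at least one sequence")
    if len(labels) == 1:
        return dict(seqs)
    subst = matrix if isinstance(matrix, np.ndarray) else _blosum_matrix(matrix)

    if len(labels) == 2:
        a, b = _align_profiles([seqs[labels[0]]], [seqs[labels[1]]],
                               subst, gap_open, gap_extend)
        return {labels[0]: a[0], labels[1]: b[0]}

    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _kmer_distance(seqs[labels[i]], seqs[labels[j]],
                                               guide_kmer)
    guide = neighbor_joining(DistanceMatrix(labels, d))

    def merge(node: TreeNode) -> tuple[list[str], list[str]]:
        """Postorder merge: returns (labels, gapped rows)."""
        if node.is_leaf:
            return [node.name], [seqs[node.name]]
        child_profiles = [merge(child) for child, _ in node.children]
        acc_labels, acc_rows = child_profiles[0]
        for nxt_labels, nxt_rows in child_profiles[1:]:
            acc_rows, nxt_rows = _align_profiles(acc_rows, nxt_rows,
                                                 subst, gap_open, gap_extend)
            acc_labels = acc_labels + nxt_labels
            acc_rows = acc_rows + nxt_rows
        return acc_labels, acc_rows

    merged_labels, merged_rows = merge(guide.root)
    aligned = dict(zip(merged_labels, merged_rows))
    return {label: aligned[label] for label in labels}
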