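"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and kept separate from the package
implementation paths it checks: exhaustive dynamic programming without the
three-matrix affine speedup, a fine-grid charge-zero scan for pI, naive
window scanners for motifs and cis-elements, and random additive trees for
neighbor-joining recovery.
"""

from __future__ import annotations

import numpy as np

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Alignment: exhaustive DP, gap of length L costs gap_open + L * gap_extend
# ---------------------------------------------------------------------------

def brute_force_local_score(a: str, b: str, score_fn,
                            gap_open: float, gap_extend: float) -> float:
    """Optimal local alignment score by trying every gap length explicitly."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            value = max(0.0, H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1]))
            for k in range(1, i + 1):
                value = max(value, H[i - k][j] - (gap_open + k * gap_extend))
            for k in range(1, j + 1):
                value = max(value, H[i][j - k] - (gap_open + k * gap_extend))
            H[i][j] = value
            best = max(best, value)
    return best


def brute_force_global_score(a: str, b: str, score_fn,
                             gap_open: float, gap_extend: float) -> float:
    """Optimal global alignment score, same exhaustive gap enumeration."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    G = [[NEG] * (m + 1) for _ in range(n + 1)]
    G[0][0] = 0.0
    for i in range(1, n + 1):
        G[i][0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        G[0][j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            value = G[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1])
            for k in range(1, i + 1):
                value = max(value, G[i - k][j] - (gap_open + k * gap_extend))
            for k in range(1, j + 1):
                value = max(value, G[i][j - k] - (gap_open + k * gap_extend))
            G[i][j] = value
    return G[n][m]


# ---------------------------------------------------------------------------
# Isoelectric point: fine-grid charge-zero scan
# ---------------------------------------------------------------------------

_POS = {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98}
_NEG = {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
_NTERM = {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82,
          "V": 7.44, "E": 7.7}
_CTERM = {"D": 4.55, "E": 4.75}


def grid_charge(seq: str, ph: np.ndarray) -> np.ndarray:
    """Vectorized net charge over a pH grid (Bjellqvist pKa set with
    residue-specific terminal corrections)."""
    charge = 1.0 / (1.0 + 10 ** (ph - _NTERM.get(seq[0], _POS["Nterm"])))
    for aa, pka in (("K", _POS["K"]), ("R", _POS["R"]), ("H", _POS["H"])):
        charge = charge + seq.count(aa) / (1.0 + 10 ** (ph - pka))
    charge = charge - 1.0 / (1.0 + 10 ** (_CTERM.get(seq[-1], _NEG["Cterm"]) - ph))
    for aa, pka in (("D", _NEG["D"]), ("E", _NEG["E"]),
                    ("C", _NEG["C"]), ("Y", _NEG["Y"])):
        charge = charge - seq.count(aa) / (1.0 + 10 ** (pka - ph))
    return charge


def grid_isoelectric_point(seq: str, step: float = 1e-5) -> float:
    ph = np.arange(0.0, 14.0 + step, step)
    charge = grid_charge(seq, ph)
    return float(ph[np.argmin(np.abs(charge))])


# ---------------------------------------------------------------------------
# Naive scanners
# ---------------------------------------------------------------------------

EXTENDED = {**{a: {a} for a in AA}, "B": {"N", "D"}, "Z": {"Q", "E"},
            "J": {"I", "L"}, "X": set(AA)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "AG", "Y": "CT", "S": "CG",
    "W": "AT", "K": "GT", "M": "AC", "B": "CGT", "D": "AGT", "H": "ACT",
    "V": "ACG", "N": "ACGT",
}


def naive_motif_hits(protein: str, consensus: str,
                     max_mismatch_fraction: float = 0.1) -> list[tuple[int, int]]:
    """Leftmost-greedy non-overlapping (1-based start, mismatches) hits."""
    width = len(consensus)
    budget = int(width * max_mismatch_fraction)
    hits = []
    pos = 0
    while pos + width <= len(protein):
        mismatches = sum(
            1 for w, c in zip(protein[pos:pos + width], consensus)
            if w not in EXTENDED[c]
        )
        if mismatches <= budget:
            hits.append((pos + 1, mismatches))
            pos += width
        else:
            pos += 1
    return hits


def naive_element_offsets(seq: str, pattern: str) -> list[int]:
    """All overlapping IUPAC occurrences, 1-based offsets."""
    width = len(pattern)
    return [
        i + 1
        for i in range(len(seq) - width + 1)
        if all(base in IUPAC[sym] for base, sym in zip(seq[i:i + width], pattern))
    ]


# ---------------------------------------------------------------------------
# Random additive trees for NJ recovery
# ---------------------------------------------------------------------------

def random_additive_matrix(n_taxa: int, rng: np.random.Generator,
                           ) -> tuple[list[str], np.ndarray]:
    """Leaf path-length matrix of a random binary tree with random
    positive branch lengths (an additive distance matrix by construction)."""
    labels = [f"T{i}" for i in range(n_taxa)]
    # grow an unrooted tree by attaching each new leaf to a random edge
    # nodes: adjacency map node -> {neighbor: length}
    adjacency: dict[str, dict[str, float]] = {}

    def connect(u, v, w):
        adjacency.setdefault(u, {})[v] = w
        adjacency.setdefault(v, {})[u] = w

    def disconnect(u, v):
        del adjacency[u][v]
        del adjacency[v][u]

    connect(labels[0], labels[1], float(rng.uniform(0.1, 2.0)))
    internal = 0
    for leaf in labels[2:]:
        edges = [(u, v) for u in adjacency for v in adjacency[u] if u < v]
        u, v = edges[int(rng.integers(len(edges)))]
        w = adjacency[u][v]
        split = float(rng.uniform(0.15, 0.85))
        node = f"I{internal}"
        internal += 1
        disconnect(u, v)
        connect(u, node, w * split)
        connect(node, v, w * (1 - split))
        connect(node, leaf, float(rng.uniform(0.1, 2.0)))

    n = len(labels)
    dist = np.zeros((n, n))
    for i, src in enumerate(labels):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            cur = stack.pop()
            for nxt, w in adjacency[cur].items():
                if nxt not in seen:
                    seen[nxt] = seen[cur] + w
                    stack.append(nxt)
        for j, dst in enumerate(labels):
            dist[i, j] = seen[dst]
    dist = (dist + dist.T) / 2.0  # exact symmetry despite float ordering
    return labels, dist
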