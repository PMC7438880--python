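"""Consensus building, subfamily assignment, and distance phylogenetics.

Trees are built from Tamura-Nei (TN93) pairwise distances with
neighbor-joining and column-bootstrap support — a deterministic,
oracle-testable substitute for maximum-likelihood search, adequate for the
qualitative cluster-membership claims the analysis makes.  Gap/N columns are
dropped per pair (pairwise deletion).  All stochastic steps take explicit
seeds (default 42).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

from .align import (
    DEFAULT_GAP_EXTEND,
    DEFAULT_GAP_OPEN,
    DEFAULT_MATCH,
    DEFAULT_MISMATCH,
    best_alignment,
    make_aligner,
)

DEFAULT_SEED = 42

_NEG_INF = -1e30


@dataclass
class MultipleAlignment:
    """Gapped rows keyed by label; all rows share one length."""

    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def labels(self) -> list[str]:
        return list(self.rows)

    def ungapped(self, label: str) -> str:
        return self.rows[label].replace("-", "")

    def sample_columns(self, indices: np.ndarray) -> "MultipleAlignment":
        return MultipleAlignment(
            {
                label: "".join(row[i] for i in indices)
                for label, row in self.rows.items()
            }
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for label, row in self.rows.items():
                fh.write(f">{label}\n{row}\n")

    @classmethod
    def from_fasta(cls, path) -> "MultipleAlignment":
        rows: dict[str, str] = {}
        label = None
        chunks: list[str] = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if label is not None:
                        rows[label] = "".join(chunks)
                    label = line[1:].split()[0]
                    chunks = []
                elif line:
                    chunks.append(line.upper())
        if label is not None:
            rows[label] = "".join(chunks)
        return cls(rows)


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    saturated: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix not symmetric")
        if (np.diag(m) != 0).any() or (m < 0).any():
            raise ValueError("distances must be non-negative with zero diagonal")
        self.matrix = m


# ---------------------------------------------------------------------------
# profile-profile global alignment (Gotoh affine gaps, numpy rows)

_SYMBOLS = "ACGT-"
_SYM_INDEX = {s: i for i, s in enumerate(_SYMBOLS)}


def _profile_of(rows: list[str]) -> np.ndarray:
    prof = np.zeros((len(rows[0]), 5))
    for row in rows:
        for j, c in enumerate(row):
            prof[j, _SYM_INDEX.get(c, 4)] += 1  # N treated as gap-neutral
    return prof / len(rows)


def _substitution_matrix(match: float, mismatch: float) -> np.ndarray:
    S = np.full((5, 5), mismatch)
    np.fill_diagonal(S, match)
    S[4, :] = 0.0
    S[:, 4] = 0.0
    return S


def _profile_align(
    p1: np.ndarray,
    p2: np.ndarray,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> tuple[float, list[str]]:
    """Global alignment of two column profiles.

    Returns (score, path) with path entries 'M' (both), 'X' (column from p1,
    gap in p2), 'Y' (column from p2, gap in p1).  Gap cost: first gap column
    ``gap_open``, each further ``gap_extend``, matching the pairwise scorer.
    """
    S = _substitution_matrix(match, mismatch)
    cols = p1 @ S @ p2.T  # (L1, L2) expected column scores
    L1, L2 = cols.shape
    M = np.full((L1 + 1, L2 + 1), _NEG_INF)
    IX = np.full((L1 + 1, L2 + 1), _NEG_INF)  # gap in p2 (consume p1)
    IY = np.full((L1 + 1, L2 + 1), _NEG_INF)  # gap in p1 (consume p2)
    M[0, 0] = 0.0
    for i in range(1, L1 + 1):
        IX[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, L2 + 1):
        IY[0, j] = gap_open + (j - 1) * gap_extend
    ext = gap_extend
    for i in range(1, L1 + 1):
        prev_best = np.maximum(np.maximum(M[i - 1], IX[i - 1]), IY[i - 1])
        M[i, 1:] = cols[i - 1] + prev_best[:-1]
        IX[i] = np.maximum(
            np.maximum(M[i - 1], IY[i - 1]) + gap_open, IX[i - 1] + ext
        )
        # IY depends on earlier columns of this row: max-plus prefix scan
        A = np.maximum(M[i], IX[i])
        j_idx = np.arange(L2 + 1)
        # gap spanning columns k+1..j costs open + (j-1-k)*extend
        B = A + gap_open - (j_idx + 1) * ext
        C = np.maximum.accumulate(B)
        IY[i, 1:] = C[:-1] + j_idx[1:] * ext
        IY[i, 0] = _NEG_INF
    # traceback
    i, j = L1, L2
    state = int(np.argmax([M[i, j], IX[i, j], IY[i, j]]))
    score = [M[i, j], IX[i, j], IY[i, j]][state]
    path: list[str] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == 0:  # M
            path.append("M")
            prev = [M[i - 1, j - 1], IX[i - 1, j - 1], IY[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:  # IX: consumed p1 column i
            path.append("X")
            if abs(IX[i, j] - (IX[i - 1, j] + ext)) < tol:
                state = 1
            elif abs(IX[i, j] - (M[i - 1, j] + gap_open)) < tol:
                state = 0
            else:
                state = 2
            i -= 1
        else:  # IY: consumed p2 column j
            path.append("Y")
            if abs(IY[i, j] - (IY[i, j - 1] + ext)) < tol:
                state = 2
            elif abs(IY[i, j] - (M[i, j - 1] + gap_open)) < tol:
                state = 0
            else:
                state = 1
            j -= 1
    path.reverse()
    return float(score), path


def _merge_rows(
    rows1: dict[str, str], rows2: dict[str, str], path: list[str]
) -> dict[str, str]:
    out: dict[str, str] = {}
    for label, row in rows1.items():
        merged = []
        k = 0
        for op in path:
            if op in ("M", "X"):
                merged.append(row[k])
                k += 1
            else:
                merged.append("-")
        out[label] = "".join(merged)
    for label, row in rows2.items():
        merged = []
        k = 0
        for op in path:
            if op in ("M", "Y"):
                merged.append(row[k])
                k += 1
            else:
                merged.append("-")
        out[label] = "".join(merged)
    return out


def _kmer_distance_matrix(seqs: list[str], k: int = 6) -> np.ndarray:
    """Fractional shared-k-mer distance used for the guide tree."""
    from collections import Counter

    counters = [Counter(s[i : i + k] for i in range(len(s) - k + 1)) for s in seqs]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = sum((counters[i] & counters[j]).values())
            denom = min(
                sum(counters[i].values()), sum(counters[j].values())
            )
            d = 1.0 - shared / denom if denom else 1.0
            D[i, j] = D[j, i] = max(0.0, d)
    return D


def _nj_join_order(D: np.ndarray) -> list[tuple[int, int, int]]:
    """Neighbor-joining join schedule as (i, j, new_index) triples.

    Indices refer to a growing node list whose first n entries are the
    leaves; ties break on the first (i, j) in scan order, so the schedule is
    deterministic.
    """
    n = D.shape[0]
    active = list(range(n))
    dist = {
        (i, j): D[i, j] for i in range(n) for j in range(n) if i < j
    }

    def d(a: int, b: int) -> float:
        return dist[(a, b)] if a < b else dist[(b, a)]

    joins: list[tuple[int, int, int]] = []
    next_index = n
    while len(active) > 2:
        m = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best = None
        best_q = math.inf
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (a, b)
        a, b = best
        for c in active:
            if c not in (a, b):
                nd = 0.5 * (d(a, c) + d(b, c) - d(a, b))
                key = (c, next_index) if c < next_index else (next_index, c)
                dist[key] = max(0.0, nd)
        joins.append((a, b, next_index))
        active.remove(a)
        active.remove(b)
        active.append(next_index)
        next_index += 1
    if len(active) == 2:
        joins.append((active[0], active[1], next_index))
    return joins


def progressive_msa(
    seqs: dict[str, str] | list[tuple[str, str]],
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> MultipleAlignment:
    """Progressive multiple alignment.

    Guide order comes from a shared-k-mer distance matrix joined by
    neighbor-joining; clusters merge by profile-profile global alignment with
    affine gaps.  Deterministic given input order.
    """
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if not items:
        raise ValueError("progressive_msa requires at least one sequence")
    if len(items) == 1:
        return MultipleAlignment({items[0][0]: items[0][1]})
    labels = [lab for lab, _ in items]
    sequences = [s.upper() for _, s in items]
    D = _kmer_distance_matrix(sequences)
    clusters: dict[int, dict[str, str]] = {
        i: {labels[i]: sequences[i]} for i in range(len(items))
    }
    for a, b, new in _nj_join_order(D):
        rows_a, rows_b = clusters.pop(a), clusters.pop(b)
        p1 = _profile_of(list(rows_a.values()))
        p2 = _profile_of(list(rows_b.values()))
        _, path = _profile_align(p1, p2, match, mismatch, gap_open, gap_extend)
        clusters[new] = _merge_rows(rows_a, rows_b, path)
    (merged,) = clusters.values()
    return MultipleAlignment({lab: merged[lab] for lab in labels})


def pairwise_global_score(
    a: str,
    b: str,
    match: float = DEFAULT_MATCH,
    mismatch: float = DEFAULT_MISMATCH,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> float:
    """Optimal global-alignment score of two sequences (same scoring)."""
    aligner = make_aligner("global", match, mismatch, gap_open, gap_extend)
    return float(aligner.score(a, b))


def consensus_from_msa(msa: MultipleAlignment, majority: float = 0.5) -> str:
    """Majority-rule consensus; a column is emitted iff its non-gap fraction
    reaches ``majority``; symbol ties break alphabetically."""
    if not msa.rows:
        raise ValueError("empty alignment")
    rows = list(msa.rows.values())
    out = []
    for j in range(msa.length):
        column = [r[j] for r in rows]
        non_gap = [c for c in column if c != "-"]
        if len(non_gap) / len(column) < majority:
            continue
        counts: dict[str, int] = {}
        for c in non_gap:
            counts[c] = counts.get(c, 0) + 1
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        out.append(best)
    return "".join(out)


def classify_subfamily(
    seq: str,
    consensus_set,
    min_identity: float = 0.80,
    margin: float = 0.03,
) -> str:
    """Assign a sequence to the subfamily consensus it matches best.

    Identity is computed with free end gaps (a truncated copy is judged over
    the region it covers).  Returns 'unassigned' when the best identity is
    below ``min_identity`` or within ``margin`` of the runner-up (candidate
    intermediate).
    """
    aligner = make_aligner(free_end_gaps=True)
    scores: list[tuple[float, str]] = []
    for cons in consensus_set:
        hit = best_alignment(aligner, cons.sequence, seq)
        identity = hit.identity if hit else 0.0
        scores.append((identity, cons.family_name))
    scores.sort(key=lambda t: (-t[0], t[1]))
    if not scores or scores[0][0] < min_identity:
        return "unassigned"
    if len(scores) > 1 and scores[0][0] - scores[1][0] < margin:
        return "unassigned"
    return scores[0][1]


# ---------------------------------------------------------------------------
# TN93 distance

_PUR = {"A", "G"}
_PYR = {"C", "T"}


def tn93_distance(row_a: str, row_b: str) -> float:
    """Tamura-Nei (1993) distance between two aligned rows.

    Columns with a gap or N in either row are excluded (pairwise deletion);
    base frequencies are empirical over the included columns of both rows.
    Returns ``nan`` when the log arguments leave their domain (saturation);
    :func:`tn93_matrix` replaces such entries for tree building.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must be aligned to equal length")
    pairs = [
        (a, b)
        for a, b in zip(row_a.upper(), row_b.upper())
        if a in "ACGT" and b in "ACGT"
    ]
    n = len(pairs)
    if n == 0:
        # disjoint coverage (e.g. opposite-end fragments): undefined, treated
        # like saturation by tn93_matrix
        return math.nan
    counts = {b: 0 for b in "ACGT"}
    p1 = p2 = q = 0
    for a, b in pairs:
        counts[a] += 1
        counts[b] += 1
        if a == b:
            continue
        pair = {a, b}
        if pair == {"A", "G"}:
            p1 += 1
        elif pair == {"C", "T"}:
            p2 += 1
        else:
            q += 1
    if p1 == p2 == q == 0:
        return 0.0
    freq = {b: counts[b] / (2 * n) for b in "ACGT"}
    gA, gC, gG, gT = freq["A"], freq["C"], freq["G"], freq["T"]
    gR, gY = gA + gG, gC + gT
    P1, P2, Q = p1 / n, p2 / n, q / n
    if min(gA, gC, gG, gT) <= 0 or gR <= 0 or gY <= 0:
        return math.nan
    k1 = 2 * gA * gG / gR
    k2 = 2 * gT * gC / gY
    w1 = 1 - P1 / k1 - Q / (2 * gR)
    w2 = 1 - P2 / k2 - Q / (2 * gY)
    w3 = 1 - Q / (2 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return math.nan
    coeff3 = 2 * (gR * gY) - k1 * gY - k2 * gR
    return -k1 * math.log(w1) - k2 * math.log(w2) - coeff3 * math.log(w3)


def tn93_matrix(msa: MultipleAlignment) -> DistanceMatrix:
    """Pairwise TN93 matrix; saturated entries become max finite + 10%."""
    labels = msa.labels
    n = len(labels)
    M = np.zeros((n, n))
    saturated = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            d = tn93_distance(msa.rows[labels[i]], msa.rows[labels[j]])
            if math.isnan(d):
                saturated[i, j] = saturated[j, i] = True
                d = math.nan
            M[i, j] = M[j, i] = d
    finite = M[np.isfinite(M)]
    cap = (finite.max() * 1.1) if finite.size and finite.max() > 0 else 1.0
    M[~np.isfinite(M)] = cap
    return DistanceMatrix(labels, M, saturated)


# ---------------------------------------------------------------------------
# neighbor joining

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Standard neighbor-joining tree (unrooted, trifurcating root).

    Negative branch-length estimates are clamped to zero with the deficit
    moved to the sister branch.
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[int, dendropy.Node] = {}
    for i, lab in enumerate(labels):
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(lab)
        nodes[i] = node
    dist: dict[tuple[int, int], float] = {
        (i, j): float(dm.matrix[i, j]) for i in range(n) for j in range(n) if i < j
    }

    def d(a: int, b: int) -> float:
        return dist[(a, b)] if a < b else dist[(b, a)]

    def clamp_pair(la: float, lb: float) -> tuple[float, float]:
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        return max(la, 0.0), max(lb, 0.0)

    active = list(range(n))
    next_index = n
    while len(active) > 3:
        m = len(active)
        r = {a: sum(d(a, b) for b in active if b != a) for a in active}
        best, best_q = None, math.inf
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * d(a, b) - r[a] - r[b]
                if q < best_q - 1e-12:
                    best_q, best = q, (a, b)
        a, b = best
        la = 0.5 * d(a, b) + (r[a] - r[b]) / (2 * (m - 2))
        lb = d(a, b) - la
        la, lb = clamp_pair(la, lb)
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        nodes[next_index] = parent
        for c in active:
            if c not in (a, b):
                nd = 0.5 * (d(a, c) + d(b, c) - d(a, b))
                key = (c, next_index) if c < next_index else (next_index, c)
                dist[key] = max(0.0, nd)
        active.remove(a)
        active.remove(b)
        active.append(next_index)
        next_index += 1
    x, y, z = active
    lx = 0.5 * (d(x, y) + d(x, z) - d(y, z))
    ly = 0.5 * (d(x, y) + d(y, z) - d(x, z))
    lz = 0.5 * (d(x, z) + d(y, z) - d(x, y))
    root = dendropy.Node()
    for idx, ln in ((x, lx), (y, ly), (z, lz)):
        root.add_child(nodes[idx])
        nodes[idx].edge.length = max(ln, 0.0)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def _bipartitions(tree: dendropy.Tree) -> dict[frozenset, dendropy.Node]:
    """Internal bipartitions as canonical frozensets of leaf labels."""
    all_leaves = frozenset(
        leaf.taxon.label for leaf in tree.leaf_node_iter()
    )
    anchor = min(all_leaves)
    out: dict[frozenset, dendropy.Node] = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if len(side) <= 1 or len(all_leaves - side) <= 1:
            continue
        canonical = side if anchor in side else all_leaves - side
        out[canonical] = node
    return out


def bootstrap_support(
    msa: MultipleAlignment,
    builder=None,
    replicates: int = 100,
    seed: int = DEFAULT_SEED,
    collapse: float | None = None,
) -> dendropy.Tree:
    """Column-bootstrap support on the tree built from the full alignment.

    ``builder`` maps an alignment to a tree (default TN93 + NJ).  Support is
    the percentage of replicate trees containing each internal bipartition,
    stored as node labels; branches below ``collapse`` (e.g. 45) collapse
    into polytomies when requested.  Bit-reproducible under a fixed seed.
    """
    if builder is None:
        def builder(m: MultipleAlignment) -> dendropy.Tree:
            return nj_tree(tn93_matrix(m))

    main = builder(msa)
    main_bips = _bipartitions(main)
    counts = {bip: 0 for bip in main_bips}
    rng = np.random.default_rng(seed)
    L = msa.length
    for _ in range(replicates):
        idx = rng.integers(0, L, size=L)
        rep_tree = builder(msa.sample_columns(idx))
        for bip in _bipartitions(rep_tree):
            if bip in counts:
                counts[bip] += 1
    to_collapse = []
    for bip, node in main_bips.items():
        support = 100.0 * counts[bip] / replicates
        node.label = f"{support:.0f}"
        zero_length = node.edge.length is not None and node.edge.length <= 0
        if collapse is not None and (support < collapse or zero_length):
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return main


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()
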