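"""Pairwise p-distances, subfamily partitioning, bootstrap divergence
summaries, split dating and terminal conservation.

The two-subfamily structure (V and W) is recovered with average-linkage
hierarchical clustering on the p-distance matrix cut into two groups at the
root — a deliberate stand-in for full phylogenetic inference: the claim being
tested is the two-clade partition and its within/between divergence, not a
tree topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

_GAPLIKE = frozenset("-N")


@dataclass
class AlignedSet:
    labels: list[str]
    sequences: list[str]          # equal length, gaps "-"
    segment_kind: str = "tpase"   # or "tir"
    span_note: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in number")
        L = {len(s) for s in self.sequences}
        if len(L) > 1:
            raise ValueError("aligned sequences must have equal length")
        bad = set("".join(self.sequences)) - set("ACGTN-")
        if bad:
            raise ValueError(f"unexpected alignment characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_matrix(self) -> np.ndarray:
        return np.array([list(s) for s in self.sequences])


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray
    deletion_mode: str = "pairwise"

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        finite = np.isfinite(m)
        if not np.allclose(m[finite], m.T[finite]):
            raise ValueError("matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.matrix).any())


@dataclass
class SubfamilyPartition:
    assignment: dict[str, str]    # label -> "V" | "W"
    support: float                # mean silhouette; ~0 flags low confidence

    def group(self, name: str) -> list[str]:
        return sorted(k for k, v in self.assignment.items() if v == name)

    @property
    def low_confidence(self) -> bool:
        return self.support < 0.25


@dataclass
class DivergenceSummary:
    within_V: tuple[float, float] | None     # (mean, bootstrap SE); None if undefined
    within_W: tuple[float, float] | None
    between: tuple[float, float]


@dataclass
class SplitDating:
    divergence_used: float
    rate: float                   # substitutions / site / Myr, per lineage
    time_mya: float = field(init=False)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.divergence_used < 0:
            raise ValueError("divergence must be non-negative")
        # two lineages accumulate divergence independently after the split
        self.time_mya = self.divergence_used / (2.0 * self.rate)


# ---------------------------------------------------------------------------
# p-distances
# ---------------------------------------------------------------------------

def p_distance_matrix(aln: AlignedSet, deletion_mode: str = "pairwise") -> DistanceMatrix:
    """Mismatch fraction over comparable sites for every pair.

    Comparable sites exclude positions holding a gap or N in either sequence
    of the pair (``pairwise`` deletion) or in any sequence (``complete``).
    A pair with zero comparable sites gets NaN (flagged missing).
    """
    n = len(aln.sequences)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if deletion_mode not in ("pairwise", "complete"):
        raise ValueError("deletion_mode must be 'pairwise' or 'complete'")
    X = aln.to_matrix()
    ok = ~np.isin(X, list(_GAPLIKE))
    if deletion_mode == "complete":
        keep = ok.all(axis=0)
        X = X[:, keep]
        ok = ok[:, keep]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = ok[i] & ok[j]
            m = int(comp.sum())
            if m == 0:
                D[i, j] = D[j, i] = np.nan
            else:
                D[i, j] = D[j, i] = np.sum(X[i, comp] != X[j, comp]) / m
    return DistanceMatrix(labels=list(aln.labels), matrix=D, deletion_mode=deletion_mode)


# ---------------------------------------------------------------------------
# subfamily clustering
# ---------------------------------------------------------------------------

def cluster_subfamilies(dm: DistanceMatrix) -> SubfamilyPartition:
    """Average-linkage clustering cut into two groups at the root.

    Deterministic for a given matrix; the group containing the
    lexicographically smallest label is named V.  Support is the mean
    silhouette width of the two-group partition (0 for degenerate ties).
    """
    if len(dm.labels) < 4:
        raise ValueError("need at least 4 sequences to partition")
    if dm.has_missing:
        raise ValueError("distance matrix has missing entries")
    order = np.argsort(dm.labels)          # lexicographic tie-breaking
    labels = [dm.labels[i] for i in order]
    M = dm.matrix[np.ix_(order, order)]
    Z = linkage(squareform(M, checks=False), method="average")
    cut = cut_tree(Z, n_clusters=2).ravel()
    if len(set(cut)) < 2:                  # fully tied matrix
        cut = np.zeros(len(labels), int)
        cut[0] = 1
    first = cut[0]
    assignment = {lab: ("V" if c == first else "W") for lab, c in zip(labels, cut)}
    try:
        support = float(silhouette_score(M, cut, metric="precomputed"))
    except ValueError:
        support = 0.0
    if not np.isfinite(support):
        support = 0.0
    return SubfamilyPartition(assignment=assignment, support=support)


# ---------------------------------------------------------------------------
# within/between divergence with bootstrap
# ---------------------------------------------------------------------------

def _pair_masks(labels: list[str], partition: SubfamilyPartition) -> dict[str, np.ndarray]:
    grp = [partition.assignment.get(lab) for lab in labels]
    n = len(labels)
    mv = np.zeros((n, n), bool)
    mw = np.zeros((n, n), bool)
    mb = np.zeros((n, n), bool)
    for a in range(n):
        for b in range(a + 1, n):
            if grp[a] is None or grp[b] is None:
                continue
            if grp[a] == grp[b]:
                (mv if grp[a] == "V" else mw)[a, b] = True
            else:
                mb[a, b] = True
    return {"V": mv, "W": mw, "B": mb}


def group_divergence(dm: DistanceMatrix, partition: SubfamilyPartition,
                     aln: AlignedSet, n_boot: int = 1000,
                     seed: int = 0) -> DivergenceSummary:
    """Within/between mean p-distance with site-resampling bootstrap SEs.

    Point estimates average the relevant unordered pairs of ``dm``; standard
    errors come from ``n_boot`` replicates that resample alignment columns
    with replacement and recompute the three means (seeded, pairwise
    deletion).  A group of size < 2 has an undefined within mean (None).
    """
    masks = _pair_masks(dm.labels, partition)
    M = dm.matrix

    def mean_over(mask: np.ndarray, mat: np.ndarray) -> float | None:
        vals = mat[mask]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else None

    point = {k: mean_over(m, M) for k, m in masks.items()}

    # per-pair mismatch/valid indicators for fast column resampling
    X = aln.to_matrix()
    ok = ~np.isin(X, list(_GAPLIKE))
    n, L = X.shape
    rng = np.random.default_rng(seed)
    sums = {k: [] for k in masks}
    pair_list = {k: np.argwhere(m) for k, m in masks.items()}
    mism = {}
    valid = {}
    for k, pl in pair_list.items():
        mism[k] = np.array([(X[a] != X[b]) & ok[a] & ok[b] for a, b in pl])
        valid[k] = np.array([ok[a] & ok[b] for a, b in pl])
    for _ in range(n_boot):
        cols = rng.integers(0, L, size=L)
        for k, pl in pair_list.items():
            if pl.size == 0:
                continue
            mm = mism[k][:, cols].sum(axis=1)
            vv = valid[k][:, cols].sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                d = np.where(vv > 0, mm / np.maximum(vv, 1), np.nan)
            d = d[np.isfinite(d)]
            if d.size:
                sums[k].append(d.mean())

    def se(k: str) -> float:
        arr = np.asarray(sums[k])
        return float(arr.std(ddof=1)) if arr.size > 1 else 0.0

    wv = (point["V"], se("V")) if point["V"] is not None and len(partition.group("V")) > 1 else None
    ww = (point["W"], se("W")) if point["W"] is not None and len(partition.group("W")) > 1 else None
    if point["B"] is None:
        raise ValueError("no between-group pairs")
    return DivergenceSummary(within_V=wv, within_W=ww, between=(point["B"], se("B")))


# ---------------------------------------------------------------------------
# dating and terminal conservation
# ---------------------------------------------------------------------------

def date_split(divergence: float, rate: float = 0.016) -> SplitDating:
    """Time of the subfamily split: divergence / (2 * rate), in Myr."""
    return SplitDating(divergence_used=divergence, rate=rate)


def terminal_conservation(aln: AlignedSet, width: int = 40) -> dict[str, int]:
    """Per-column identity classes over the terminal segment.

    Counts columns whose majority-base frequency (gaps counted as
    mismatches) reaches 100%, >=80% and >=60%.
    """
    if aln.length != width:
        raise ValueError(f"alignment must be exactly {width} columns")
    X = aln.to_matrix()
    n = X.shape[0]
    out = {"n100": 0, "n80": 0, "n60": 0}
    for j in range(X.shape[1]):
        col = X[:, j]
        freqs = [np.sum(col == b) / n for b in "ACGT"]
        top = max(freqs)
        if top == 1.0:
            out["n100"] += 1
        if top >= 0.8:
            out["n80"] += 1
        if top >= 0.6:
            out["n60"] += 1
    return out


def consensus_difference(cons_a: str, cons_b: str) -> float:
    """Fraction of positions at which two consensus strings differ."""
    if len(cons_a) != len(cons_b):
        raise ValueError("consensus strings must have equal length")
    return sum(a != b for a, b in zip(cons_a, cons_b)) / len(cons_a)


def linkage_newick(dm: DistanceMatrix) -> str:
    """Average-linkage dendrogram of the matrix as a newick string."""
    if dm.has_missing:
        raise ValueError("distance matrix has missing entries")
    Z = linkage(squareform(dm.matrix, checks=False), method="average")
    n = len(dm.labels)
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return dm.labels[i]
        a, b, h, _ = Z[i - n]
        ba = max(0.0, h / 2 - heights[int(a)])
        bb = max(0.0, h / 2 - heights[int(b)])
        heights[i] = h / 2
        return f"({node(int(a))}:{ba:.6f},{node(int(b))}:{bb:.6f})"

    for i in range(len(Z)):
        heights[n + i] = 0.0
    return node(n + len(Z) - 1) + ";"
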