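"""Community-analysis engine: dissimilarities, ordination, permutation
tests, clustering and set overlaps.

The assemblage workflow mirrors standard practice in community ecology:

1. species x habitat record counts are recoded to a three-class
   abundance scale (0 = absent, 1 = one record, 2 = more than one) to
   damp observation bias while retaining more than presence/absence;
2. species known from a single habitat type are dropped;
3. Bray-Curtis dissimilarities feed a two-dimensional non-metric
   multidimensional scaling (NMDS, Kruskal stress-1 with monotone
   regression by pool-adjacent-violators) and multi-response permutation
   procedures (MRPP) with a permutation null and Bonferroni correction;
4. host-tree assemblages are clustered by UPGMA (average linkage).

NMDS, PAVA, MRPP and UPGMA are implemented here so that their numerical
conventions (tie-breaks, null enumeration, weighting) are explicit and
testable; Bray-Curtis delegates to scipy's pairwise-distance kernel.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from porelist.records import BandedCount, OccurrenceRecord, habitat_key

__all__ = [
    "DissimilarityMatrix", "OrdinationResult", "MrppResult", "Dendrogram",
    "OverlapReport", "three_class_recode", "habitat_matrix",
    "filter_single_habitat_species", "bray_curtis", "pava_monotone",
    "nmds", "mrpp", "bonferroni", "upgma", "overlap_counts",
]


# ---------------------------------------------------------------------------
# Recoding and matrix assembly

def three_class_recode(count: Union[int, BandedCount]) -> int:
    """Recode a record count to the three-class scale:
    0 = no records, 1 = one record, 2 = more than one record.

    Censored banded counts ('>T' with T >= 2) imply more than one record.
    """
    if isinstance(count, BandedCount):
        if count.censored:
            return 2
        count = count.value
    if count < 0:
        raise ValueError("negative count")
    return min(int(count), 2)


def habitat_matrix(records: Iterable[OccurrenceRecord],
                   exclude_early_successional: bool = True,
                   recode: bool = True) -> pd.DataFrame:
    """Species x habitat-type table from occurrence records.

    Habitat types are habitat keys (stand triples or pooled special
    habitats); early-successional stands are excluded by default because
    the habitat-gradient analysis targets stands older than 20 years.
    Values are three-class recoded counts unless ``recode=False``.
    Records without habitat information are skipped.
    """
    cells: dict[tuple[str, str], int] = {}
    for rec in records:
        try:
            key = habitat_key(rec)
        except Exception:
            continue
        if exclude_early_successional and key.early_successional:
            continue
        cell = (rec.species_id, str(key))
        cells[cell] = cells.get(cell, 0) + 1
    if not cells:
        return pd.DataFrame(dtype=int)
    species = sorted({s for s, _ in cells})
    habitats = sorted({h for _, h in cells})
    mat = pd.DataFrame(0, index=species, columns=habitats, dtype=int)
    for (s, h), n in cells.items():
        mat.loc[s, h] = n
    if recode:
        mat = mat.map(three_class_recode)
    return mat


def filter_single_habitat_species(counts: pd.DataFrame
                                  ) -> tuple[pd.DataFrame, list[str]]:
    """Drop species recorded from a single habitat type.

    Returns the filtered species x habitat matrix and the list of
    removed species.
    """
    present = (counts > 0).sum(axis=1)
    removed = sorted(counts.index[present <= 1])
    return counts.drop(index=removed), removed


# ---------------------------------------------------------------------------
# Dissimilarity

@dataclass
class DissimilarityMatrix:
    labels: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.labels)
        if self.D.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.D, self.D.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have zero diagonal")
        if (self.D < -1e-12).any():
            raise ValueError("dissimilarities must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.D, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.labels, columns=self.labels)


def bray_curtis(X: Union[np.ndarray, pd.DataFrame],
                labels: Optional[Sequence[str]] = None) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarities between the rows (samples) of *X*:

        D[i, j] = sum |x_i - x_j| / sum (x_i + x_j)

    Entries must be non-negative; an all-zero row is an error because
    its dissimilarity to anything is undefined.
    """
    if isinstance(X, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in X.index]
        X = X.to_numpy(dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    if labels is None:
        labels = [str(i) for i in range(X.shape[0])]
    if (X < 0).any():
        raise ValueError("negative entries are not allowed")
    zero_rows = np.flatnonzero(X.sum(axis=1) == 0)
    if zero_rows.size:
        raise ValueError(
            f"all-zero sample(s): {', '.join(labels[i] for i in zero_rows)}")
    D = squareform(pdist(X, metric="braycurtis"))
    return DissimilarityMatrix(labels=list(labels), D=D)


# ---------------------------------------------------------------------------
# Monotone regression (pool adjacent violators)

def pava_monotone(y: Sequence[float],
                  weights: Optional[Sequence[float]] = None) -> np.ndarray:
    """Weighted least-squares non-decreasing fit of *y* by
    pool-adjacent-violators.  Idempotent; already-monotone input is
    returned unchanged.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape or (w <= 0).any():
            raise ValueError("weights must be positive and match y")
    # blocks of (value, weight, length), merged while out of order
    values: list[float] = []
    wsum: list[float] = []
    length: list[int] = []
    for yi, wi in zip(y, w):
        values.append(yi)
        wsum.append(wi)
        length.append(1)
        while len(values) > 1 and values[-2] > values[-1]:
            v = (values[-2] * wsum[-2] + values[-1] * wsum[-1]) / (wsum[-2] + wsum[-1])
            wsum[-2] += wsum[-1]
            length[-2] += length[-1]
            values[-2] = v
            del values[-1], wsum[-1], length[-1]
    out = np.empty_like(y)
    pos = 0
    for v, k in zip(values, length):
        out[pos:pos + k] = v
        pos += k
    return out


# ---------------------------------------------------------------------------
# Non-metric multidimensional scaling

@dataclass
class OrdinationResult:
    labels: list[str]
    configuration: np.ndarray  # n x k, centred, principal-axis rotated
    stress: float              # Kruskal stress-1
    n_starts: int
    best_start: int
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        cols = [f"axis{i + 1}" for i in range(self.configuration.shape[1])]
        return pd.DataFrame(self.configuration, index=self.labels, columns=cols)


def _stress1(d: np.ndarray, dhat: np.ndarray) -> float:
    denom = float(np.sum(d * d))
    if denom == 0:
        return 0.0
    return math.sqrt(float(np.sum((d - dhat) ** 2)) / denom)


def _principal_axes(X: np.ndarray) -> np.ndarray:
    """Centre and rotate so axis 1 carries maximal variance, with a
    deterministic sign convention (largest-magnitude coordinate on each
    axis is positive)."""
    X = X - X.mean(axis=0)
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    X = X @ Vt.T
    for j in range(X.shape[1]):
        i = int(np.argmax(np.abs(X[:, j])))
        if X[i, j] < 0:
            X[:, j] = -X[:, j]
    return X


def _metric_start(D: np.ndarray, k: int) -> np.ndarray:
    """Classical (metric) scaling start: eigendecomposition of the
    doubly-centred squared-dissimilarity matrix."""
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(vals)


def nmds(D: DissimilarityMatrix, k: int = 2, n_starts: int = 20,
         max_iter: int = 300, tol: float = 1e-7, seed: int = 0,
         metric_start: bool = True) -> OrdinationResult:
    """Kruskal non-metric multidimensional scaling.

    Minimises stress-1 = sqrt(sum (d - dhat)^2 / sum d^2), where d are
    configuration distances and dhat their least-squares monotone fit
    against the input dissimilarity order (primary tie approach: ties in
    the input may be fitted unequally).  Each start is improved by
    Guttman-transform iterations with the stress tracked explicitly, so
    the recorded stress never increases within a start.  The best of
    ``n_starts`` random starts (plus one metric-scaling start unless
    disabled) is returned, centred and rotated to principal axes.
    """
    n = D.n
    if n <= k:
        raise ValueError(f"need more than k={k} samples, got {n}")
    dis = D.condensed()
    order = np.argsort(dis, kind="stable")
    rng = np.random.default_rng(seed)

    def fit_disparities(d: np.ndarray) -> np.ndarray:
        dhat = np.empty_like(d)
        dhat[order] = pava_monotone(d[order])
        return dhat

    def run_start(X: np.ndarray) -> tuple[np.ndarray, float, bool]:
        d = pdist(X)
        dhat = fit_disparities(d)
        stress = _stress1(d, dhat)
        converged = False
        for _ in range(max_iter):
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d > 0, dhat / d, 0.0)
            R = squareform(ratio, checks=False)
            Bmat = -R
            np.fill_diagonal(Bmat, R.sum(axis=1))
            X_new = (Bmat @ X) / n
            d_new = pdist(X_new)
            dhat_new = fit_disparities(d_new)
            stress_new = _stress1(d_new, dhat_new)
            if stress_new > stress:      # keep the monotone guarantee
                converged = True
                break
            if stress - stress_new < tol:
                X, stress = X_new, stress_new
                converged = True
                break
            X, d, dhat, stress = X_new, d_new, dhat_new, stress_new
        return X, stress, converged

    starts: list[np.ndarray] = []
    if metric_start:
        starts.append(_metric_start(D.D, k))
    while len(starts) < n_starts + (1 if metric_start else 0):
        starts.append(rng.uniform(-1.0, 1.0, size=(n, k)))

    best: Optional[tuple[np.ndarray, float, bool, int]] = None
    for idx, X0 in enumerate(starts):
        X, stress, conv = run_start(X0.copy())
        if best is None or stress < best[1] - 1e-15:
            best = (X, stress, conv, idx)
    assert best is not None
    X, stress, conv, idx = best
    return OrdinationResult(labels=list(D.labels),
                            configuration=_principal_axes(X),
                            stress=stress, n_starts=len(starts),
                            best_start=idx, converged=conv)


# ---------------------------------------------------------------------------
# Multi-response permutation procedure

class MrppWeight(str, enum.Enum):
    """Group weighting for the observed within-group dissimilarity:
    proportional to n_g (the common default), to n_g - 1, or equal."""

    group_size = "group_size"
    group_size_minus_one = "group_size_minus_one"
    equal = "equal"


@dataclass
class MrppResult:
    delta_obs: float
    expected_delta: float
    A: float
    p_raw: float
    p_adjusted: float
    B: int            # permutations evaluated (exhaustive count if exact)
    exact: bool
    seed: Optional[int]
    weight: MrppWeight


def bonferroni(p: Union[float, Sequence[float]], m: int
               ) -> Union[float, np.ndarray]:
    """Bonferroni adjustment: min(1, m * p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    arr = np.asarray(p, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.minimum(1.0, m * arr)
    return float(out) if np.isscalar(p) or out.ndim == 0 else out


def _group_masks(labels: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
    uniq = np.unique(labels)
    masks = [labels == g for g in uniq]
    sizes = np.array([m.sum() for m in masks])
    return masks, sizes


def _delta_for_masks(D: np.ndarray, masks: Sequence[np.ndarray],
                     w: np.ndarray) -> float:
    delta = 0.0
    for mask, wg in zip(masks, w):
        sub = D[np.ix_(mask, mask)]
        n_g = mask.sum()
        delta += wg * sub.sum() / (n_g * (n_g - 1))
    return delta


def _weights(sizes: np.ndarray, weight: MrppWeight) -> np.ndarray:
    if weight is MrppWeight.group_size:
        w = sizes.astype(float)
    elif weight is MrppWeight.group_size_minus_one:
        w = sizes.astype(float) - 1.0
    else:
        w = np.ones_like(sizes, dtype=float)
    return w / w.sum()


def _assignments(indices: tuple[int, ...], sizes: Sequence[int]):
    """Yield all distinct ordered partitions of *indices* into groups of
    the given sizes."""
    if len(sizes) == 1:
        yield (indices,)
        return
    first, rest_sizes = sizes[0], sizes[1:]
    for combo in itertools.combinations(indices, first):
        rest = tuple(i for i in indices if i not in combo)
        for tail in _assignments(rest, rest_sizes):
            yield (combo,) + tail


def mrpp(D: DissimilarityMatrix, groups: Sequence, B: int = 999,
         weight: Union[MrppWeight, str] = MrppWeight.group_size,
         seed: int = 0, m_comparisons: int = 1,
         method: str = "auto", exhaustive_limit: int = 10_000) -> MrppResult:
    """Multi-response permutation procedure.

    delta_obs is the weighted mean within-group dissimilarity (weights
    w_g proportional to group size by default).  The null distribution
    relabels samples: exhaustively over all distinct assignments when
    their number is at most *exhaustive_limit* (p = proportion of
    relabelings with delta <= delta_obs, the observed one included),
    otherwise by B seeded Monte-Carlo permutations with the add-one
    estimator p = (1 + count) / (B + 1).  The chance-corrected
    within-group agreement is A = 1 - delta_obs / expected_delta.
    ``m_comparisons`` Bonferroni-adjusts the reported p.
    """
    weight = MrppWeight(weight)
    labels = np.asarray(groups)
    if len(labels) != D.n:
        raise ValueError("group labels must match the matrix size")
    masks, sizes = _group_masks(labels)
    if len(masks) < 2:
        raise ValueError("need at least two groups")
    if (sizes < 2).any():
        raise ValueError("every group needs at least two members")
    w = _weights(sizes, weight)
    delta_obs = _delta_for_masks(D.D, masks, w)

    n = D.n
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(int(s))
    exact = method == "exact" or (method == "auto" and total <= exhaustive_limit)
    if method not in ("auto", "exact", "montecarlo"):
        raise ValueError(f"unknown method {method!r}")

    if exact:
        deltas = np.empty(total)
        idx_all = tuple(range(n))
        for i, assignment in enumerate(_assignments(idx_all, [int(s) for s in sizes])):
            perm_masks = []
            for members in assignment:
                mask = np.zeros(n, dtype=bool)
                mask[list(members)] = True
                perm_masks.append(mask)
            deltas[i] = _delta_for_masks(D.D, perm_masks, w)
        p_raw = float(np.sum(deltas <= delta_obs + 1e-12) / total)
        expected = float(deltas.mean())
        B_used, used_seed = total, None
    else:
        rng = np.random.default_rng(seed)
        count = 0
        deltas = np.empty(B)
        for b in range(B):
            perm = rng.permutation(labels)
            perm_masks, _ = _group_masks(perm)
            deltas[b] = _delta_for_masks(D.D, perm_masks, w)
        count = int(np.sum(deltas <= delta_obs + 1e-12))
        p_raw = (1 + count) / (B + 1)
        expected = float(deltas.mean())
        B_used, used_seed = B, seed

    A = 1.0 - delta_obs / expected if expected > 0 else 0.0
    return MrppResult(delta_obs=delta_obs, expected_delta=expected, A=A,
                      p_raw=p_raw,
                      p_adjusted=float(bonferroni(p_raw, m_comparisons)),
                      B=B_used, exact=exact, seed=used_seed, weight=weight)


# ---------------------------------------------------------------------------
# UPGMA clustering

@dataclass
class Dendrogram:
    """Agglomerative tree: leaves 0..n-1, internal nodes numbered onward;
    merges recorded in order as (node_a, node_b, height)."""

    leaf_labels: list[str]
    merges: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def _members(self) -> dict[int, list[int]]:
        members = {i: [i] for i in range(self.n_leaves)}
        for idx, (a, b, _) in enumerate(self.merges):
            members[self.n_leaves + idx] = members[a] + members[b]
        return members

    def cophenetic_matrix(self) -> np.ndarray:
        """Matrix of heights at which leaf pairs first join."""
        n = self.n_leaves
        C = np.zeros((n, n))
        members = {i: [i] for i in range(n)}
        for idx, (a, b, h) in enumerate(self.merges):
            for i in members[a]:
                for j in members[b]:
                    C[i, j] = C[j, i] = h
            members[n + idx] = members[a] + members[b]
        return C

    def cophenetic(self, i: int, j: int) -> float:
        return float(self.cophenetic_matrix()[i, j])

    def cut(self, k: int) -> np.ndarray:
        """Cluster assignment of the leaves after undoing the last
        k - 1 merges."""
        n = self.n_leaves
        if not 1 <= k <= n:
            raise ValueError("k out of range")
        members = self._members()
        active = set(range(n))
        for idx, (a, b, _) in enumerate(self.merges[: n - k]):
            active -= {a, b}
            active.add(n + idx)
        out = np.empty(n, dtype=int)
        for lbl, node in enumerate(sorted(active)):
            out[members[node]] = lbl
        return out

    def to_newick(self, halve_heights: bool = False) -> str:
        """Newick string with branch lengths derived from merge heights
        (optionally halved, the convention for ultrametric trees where a
        merge height is the sum of the two branch lengths)."""
        scale = 0.5 if halve_heights else 1.0
        height = {i: 0.0 for i in range(self.n_leaves)}
        text = {i: lbl for i, lbl in enumerate(self.leaf_labels)}
        node = self.n_leaves
        for a, b, h in self.merges:
            height[node] = h
            la = (height[node] - height[a]) * scale
            lb = (height[node] - height[b]) * scale
            text[node] = f"({text[a]}:{la:.6g},{text[b]}:{lb:.6g})"
            node += 1
        root = node - 1 if self.merges else 0
        return text[root] + ";"


def upgma(D: DissimilarityMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomerative clustering.

    The closest pair of clusters is merged repeatedly; inter-cluster
    distance is the size-weighted arithmetic mean over all cross pairs.
    Distance ties break deterministically toward the pair with the
    lowest cluster indices.  Merge heights are the merge distances.
    """
    n = D.n
    if n < 2:
        raise ValueError("need at least two items")
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D.D[i, j])
    size = {i: 1 for i in range(n)}
    active = list(range(n))
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best_pair, best_d = None, math.inf
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                a, b = active[ai], active[aj]
                d = dist[(a, b)]
                if d < best_d - 1e-15:
                    best_pair, best_d = (a, b), d
        a, b = best_pair
        merges.append((a, b, best_d))
        for c in active:
            if c in (a, b):
                continue
            da = dist[(min(a, c), max(a, c))]
            db = dist[(min(b, c), max(b, c))]
            dnew = (size[a] * da + size[b] * db) / (size[a] + size[b])
            dist[(c, next_id)] = dnew
        size[next_id] = size[a] + size[b]
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return Dendrogram(leaf_labels=list(D.labels), merges=merges)


# ---------------------------------------------------------------------------
# Habitat set overlaps

@dataclass
class OverlapEntry:
    combination: tuple[str, ...]
    n_in_all: int     # species found in every member type
    n_unique: int     # of those, species found in no other type


@dataclass
class OverlapReport:
    entries: list[OverlapEntry]

    def as_dict(self) -> dict[str, dict[str, int]]:
        return {"+".join(e.combination): {"in_all": e.n_in_all,
                                          "unique": e.n_unique}
                for e in self.entries}


def overlap_counts(species_lists: Mapping[str, Iterable[str]],
                   combinations: Sequence[Sequence[str]]) -> OverlapReport:
    """Set-overlap counts among habitat-type species lists.

    For each requested combination C: ``n_in_all`` is the number of
    species present in every type of C, and ``n_unique`` the number of
    those found in no type outside C.
    """
    sets = {k: set(v) for k, v in species_lists.items()}
    entries = []
    for combo in combinations:
        combo = tuple(combo)
        for t in combo:
            if t not in sets:
                raise ValueError(f"unknown habitat type {t!r}")
        inter = set.intersection(*(sets[t] for t in combo))
        others = set().union(*(sets[t] for t in sets if t not in combo)) \
            if len(sets) > len(set(combo)) else set()
        entries.append(OverlapEntry(combination=combo,
                                    n_in_all=len(inter),
                                    n_unique=len(inter - others)))
    return OverlapReport(entries=entries)
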