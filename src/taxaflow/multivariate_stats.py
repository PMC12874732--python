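"""Permutation multivariate statistics from first principles.

Implements the statistical machinery used on the functional and taxonomic
profiles: Bray-Curtis and Euclidean distance matrices, one-way PERMANOVA
with permutation p-values (exact enumeration on small designs), pairwise
comparisons with a Monte-Carlo fallback when free permutations are scarce,
principal coordinates analysis (PCoA), non-metric multidimensional scaling
(NMDS, Kruskal stress-1 by iterative majorization with monotone regression)
and the thresholded Pearson correlation screen between gene profiles and
soil properties.

PERMANOVA decomposition on an ``n x n`` distance matrix with ``g`` groups:

    SS_total  = sum_{i<j} d_ij^2 / n
    SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
    pseudo-F  = (SS_among / (g - 1)) / (SS_within / (n - g))

Sampled p-values use the (1 + b) / (1 + m) convention (the observed
statistic counts as one permutation, so p is never 0); ties with the
observed statistic count as extreme.  When the number of distinct
relabelings (groups of equal size counted unordered) does not exceed the
requested permutation count, full enumeration replaces sampling and the
p-value is exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.isotonic import IsotonicRegression

from .types import SoilProperties, UnstratifiedTable

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "OrdinationResult",
    "bray_curtis",
    "euclidean",
    "permanova",
    "pairwise_permanova",
    "count_distinct_relabelings",
    "pcoa",
    "nmds",
    "correlation_screen",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with sample ids."""

    values: np.ndarray
    ids: tuple[str, ...]
    metric: str = "unknown"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.ids):
            raise ValueError("ids length does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal must be zero")
        if v.size and v.min() < -1e-12:
            raise ValueError("distances must be non-negative")
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.ids)

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        pos = [self.ids.index(s) for s in keep]
        return DistanceMatrix(
            self.values[np.ix_(pos, pos)], tuple(keep), self.metric
        )


def _as_matrix(data) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), tuple(map(str, data.index))
    arr = np.asarray(data, dtype=float)
    return arr, tuple(f"s{i}" for i in range(arr.shape[0]))


def bray_curtis(abundance) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(x, y) = sum|x - y| / sum(x + y) on a
    samples x features abundance matrix (rows are samples)."""
    arr, ids = _as_matrix(abundance)
    if arr.size and arr.min() < 0:
        raise ValueError("Bray-Curtis requires non-negative abundances")
    zero_rows = np.where(arr.sum(axis=1) == 0)[0]
    if len(zero_rows) >= 2:
        a, b = ids[zero_rows[0]], ids[zero_rows[1]]
        raise ValueError(
            f"samples {a!r} and {b!r} are both all-zero; their distance is undefined"
        )
    d = squareform(pdist(arr, metric="braycurtis"))
    return DistanceMatrix(d, ids, "bray_curtis")


def euclidean(data, standardize: bool = False) -> DistanceMatrix:
    """Euclidean distance, optionally on z-scored columns (unit-variance
    standardisation makes the result invariant to per-column rescaling, the
    appropriate treatment for soil properties on disparate scales)."""
    arr, ids = _as_matrix(data)
    if standardize:
        sd = arr.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0  # constant columns carry no distance information
        arr = (arr - arr.mean(axis=0)) / sd
    d = squareform(pdist(arr, metric="euclidean"))
    return DistanceMatrix(d, ids, "euclidean")


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaResult:
    pseudo_F: float
    p_perm: float
    n_permutations_used: int
    df_among: int
    df_within: int
    method: str  # "exact" | "sampled"
    p_montecarlo: float | None = None
    degenerate: bool = False


def _group_layout(groups: Sequence[str]) -> tuple[np.ndarray, list[str], np.ndarray]:
    labels = list(dict.fromkeys(groups))
    codes = np.array([labels.index(g) for g in groups])
    sizes = np.array([(codes == i).sum() for i in range(len(labels))])
    return codes, labels, sizes


def _F_from_codes(d2: np.ndarray, codes: np.ndarray, sizes: np.ndarray) -> float:
    n = d2.shape[0]
    g = len(sizes)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for gi in range(g):
        idx = np.where(codes == gi)[0]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * sizes[gi])
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return math.inf if ss_among > 0 else math.nan
    return (ss_among / (g - 1)) / (ss_within / (n - g))


def count_distinct_relabelings(sizes: Sequence[int]) -> int:
    """Number of distinct relabelings: multinomial(n; sizes) with groups of
    equal size counted once ("free permutations" of an unordered design)."""
    n = sum(sizes)
    total = math.factorial(n)
    for s in sizes:
        total //= math.factorial(s)
    counts: dict[int, int] = {}
    for s in sizes:
        counts[s] = counts.get(s, 0) + 1
    for m in counts.values():
        total //= math.factorial(m)
    return total


def _class_partitions(items: tuple, s: int, m: int) -> Iterator[tuple]:
    """Unordered partitions of ``items`` (len = s*m) into m groups of size s;
    canonical: each group contains the smallest element not yet used."""
    if m == 0:
        yield ()
        return
    first = items[0]
    for rest in combinations(items[1:], s - 1):
        grp = (first,) + rest
        used = set(grp)
        remaining = tuple(x for x in items if x not in used)
        for tail in _class_partitions(remaining, s, m - 1):
            yield (grp,) + tail


def _all_partitions(items: tuple, size_classes: list[tuple[int, int]]) -> Iterator[tuple]:
    if not size_classes:
        yield ()
        return
    (s, m), rest = size_classes[0], size_classes[1:]
    for chosen in combinations(items, s * m):
        used = set(chosen)
        remaining = tuple(x for x in items if x not in used)
        for groups in _class_partitions(chosen, s, m):
            for tail in _all_partitions(remaining, rest):
                yield groups + tail


def _exact_p(d2: np.ndarray, sizes: np.ndarray, f_obs: float) -> tuple[float, int]:
    n = d2.shape[0]
    counts: dict[int, int] = {}
    for s in sizes:
        counts[int(s)] = counts.get(int(s), 0) + 1
    size_classes = sorted(counts.items())
    hits = 0
    total = 0
    sizes_sorted = np.array(
        [s for s, m in size_classes for _ in range(m)], dtype=int
    )
    for partition in _all_partitions(tuple(range(n)), size_classes):
        codes = np.empty(n, dtype=int)
        for gi, grp in enumerate(partition):
            codes[list(grp)] = gi
        f = _F_from_codes(d2, codes, sizes_sorted)
        total += 1
        if _ge_with_ties(f, f_obs):
            hits += 1
    return hits / total, total


def _ge_with_ties(f: float, f_obs: float) -> bool:
    if math.isnan(f):
        return False
    if math.isinf(f_obs):
        return math.isinf(f)
    return f >= f_obs - 1e-12 * max(1.0, abs(f_obs))


def _sampled_F(
    d2: np.ndarray,
    codes: np.ndarray,
    sizes: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Pseudo-F for ``n_perm`` random relabelings, batched."""
    n = d2.shape[0]
    g = len(sizes)
    onehot = np.zeros((n, g))
    onehot[np.arange(n), codes] = 1.0
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    Gp = onehot[perms]  # (P, n, g)
    T = np.einsum("ij,pjg->pig", d2, Gp)
    within_g = (Gp * T).sum(axis=1) / (2 * sizes)  # (P, g)
    ss_within = within_g.sum(axis=1)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_among = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_among / (g - 1)) / (ss_within / (n - g))
    f[ss_within <= 0] = np.inf
    return f


def permanova(
    d: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int | np.random.SeedSequence | None = 0,
) -> PermanovaResult:
    """One-way PERMANOVA with permutation p-value.

    Uses exact enumeration of all distinct relabelings when their number does
    not exceed ``n_perm``; otherwise samples ``n_perm`` random relabelings
    and reports p = (1 + b) / (1 + n_perm).
    """
    if len(groups) != d.n:
        raise ValueError("groups length does not match distance matrix")
    codes, labels, sizes = _group_layout(groups)
    g = len(labels)
    n = d.n
    if g < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if n < 3:
        raise ValueError("PERMANOVA needs at least three samples")
    d2 = d.values**2
    df_among, df_within = g - 1, n - g
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    if ss_total <= 1e-300:
        return PermanovaResult(
            pseudo_F=math.nan,
            p_perm=1.0,
            n_permutations_used=0,
            df_among=df_among,
            df_within=df_within,
            method="degenerate",
            degenerate=True,
        )
    f_obs = _F_from_codes(d2, codes, sizes)
    n_distinct = count_distinct_relabelings([int(s) for s in sizes])
    if n_distinct <= n_perm:
        p, total = _exact_p(d2, sizes, f_obs)
        return PermanovaResult(
            pseudo_F=f_obs,
            p_perm=p,
            n_permutations_used=total,
            df_among=df_among,
            df_within=df_within,
            method="exact",
        )
    rng = np.random.default_rng(seed)
    f_perm = _sampled_F(d2, codes, sizes, n_perm, rng)
    b = int(sum(_ge_with_ties(f, f_obs) for f in f_perm))
    return PermanovaResult(
        pseudo_F=f_obs,
        p_perm=(1 + b) / (1 + n_perm),
        n_permutations_used=n_perm,
        df_among=df_among,
        df_within=df_within,
        method="sampled",
    )


def pairwise_permanova(
    d: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    montecarlo_min_perms: int = 100,
    montecarlo_draws: int = 10_000,
    seed: int | np.random.SeedSequence | None = 0,
) -> pd.DataFrame:
    """Pairwise two-group comparisons (multivariate analogue of the t-test:
    pseudo-t = sqrt(pseudo-F) on each pair's sub-matrix).

    When a pair's number of free permutations falls below
    ``montecarlo_min_perms`` (e.g. 10 for a 3-vs-3 design), a Monte-Carlo
    p-value is additionally reported from ``montecarlo_draws`` random
    relabelings drawn with replacement.
    """
    if len(groups) != d.n:
        raise ValueError("groups length does not match distance matrix")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    group_arr = np.asarray(list(groups))
    labels = list(dict.fromkeys(groups))
    rows = []
    for (a, b), sub_seed in zip(
        combinations(labels, 2), ss.spawn(math.comb(len(labels), 2))
    ):
        keep = [i for i, grp in enumerate(group_arr) if grp in (a, b)]
        if len(keep) < 2:
            warnings.warn(f"pair ({a}, {b}) has fewer than 2 members; skipped")
            continue
        ids_sub = [d.ids[i] for i in keep]
        d_sub = d.submatrix(ids_sub)
        groups_sub = [group_arr[i] for i in keep]
        try:
            res = permanova(d_sub, groups_sub, n_perm=n_perm, seed=sub_seed)
        except ValueError as exc:
            warnings.warn(f"pair ({a}, {b}) skipped: {exc}")
            continue
        sizes = [groups_sub.count(a), groups_sub.count(b)]
        n_free = count_distinct_relabelings(sizes)
        p_mc = None
        if n_free < montecarlo_min_perms and not res.degenerate:
            codes, _, size_arr = _group_layout(groups_sub)
            d2 = d_sub.values**2
            rng = np.random.default_rng(sub_seed.spawn(1)[0])
            f_draws = _sampled_F(d2, codes, size_arr, montecarlo_draws, rng)
            b_mc = int(sum(_ge_with_ties(f, res.pseudo_F) for f in f_draws))
            p_mc = (1 + b_mc) / (1 + montecarlo_draws)
        pseudo_t = (
            math.sqrt(res.pseudo_F)
            if res.pseudo_F == res.pseudo_F and not math.isinf(res.pseudo_F)
            else res.pseudo_F
        )
        rows.append(
            {
                "group1": a,
                "group2": b,
                "pseudo_t": pseudo_t,
                "pseudo_F": res.pseudo_F,
                "p_perm": res.p_perm,
                "p_montecarlo": p_mc,
                "n_free_permutations": n_free,
                "method": res.method,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ordination


@dataclass
class OrdinationResult:
    coordinates: np.ndarray  # n x k
    ids: tuple[str, ...]
    eigenvalues: np.ndarray | None = None
    percent_variance: np.ndarray | None = None
    stress: float | None = None
    converged: bool = True
    stress_history: list[float] | None = None

    def frame(self) -> pd.DataFrame:
        k = self.coordinates.shape[1]
        return pd.DataFrame(
            self.coordinates,
            index=pd.Index(self.ids, name="sample_id"),
            columns=[f"axis{i + 1}" for i in range(k)],
        )


def pcoa(
    d: DistanceMatrix, variance_denominator: str = "positive"
) -> OrdinationResult:
    """Principal coordinates analysis by Gower double-centering.

    Axes are ordered by descending eigenvalue and carry coordinates
    ``eigenvector * sqrt(eigenvalue)`` for positive eigenvalues only.
    Percent variance per axis is computed over the positive eigenvalues
    (``variance_denominator="absolute"`` divides by the sum of |eigenvalue|
    instead).  Sign convention: the first nonzero loading of each axis is
    non-negative.
    """
    if variance_denominator not in ("positive", "absolute"):
        raise ValueError("variance_denominator must be 'positive' or 'absolute'")
    n = d.n
    if n < 3:
        raise ValueError("PCoA needs at least three samples")
    d2 = d.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, abs(eigvals).max(initial=0.0) * 1e-12)
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    for j in range(coords.shape[1]):
        col = coords[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            coords[:, j] = -col
    denom = eigvals[pos].sum() if variance_denominator == "positive" else np.abs(
        eigvals
    ).sum()
    percent = 100.0 * eigvals[pos] / denom if denom > 0 else np.zeros(pos.sum())
    return OrdinationResult(
        coordinates=coords,
        ids=d.ids,
        eigenvalues=eigvals,
        percent_variance=percent,
    )


def _stress1(dvec: np.ndarray, dhat: np.ndarray) -> float:
    denom = (dvec**2).sum()
    if denom == 0:
        return 0.0
    return math.sqrt(((dvec - dhat) ** 2).sum() / denom)


def _monotone_fit(diss: np.ndarray, dvec: np.ndarray) -> np.ndarray:
    order = np.argsort(diss, kind="stable")
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(np.arange(len(dvec)), dvec[order])
    dhat = np.empty_like(dvec)
    dhat[order] = fitted
    return dhat


def nmds(
    d: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 8,
    max_iter: int = 300,
    seed: int | np.random.SeedSequence | None = 0,
    tol: float = 1e-7,
) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Alternates monotone (isotonic) regression of configuration distances on
    the rank order of the input dissimilarities with a Guttman majorization
    update.  The recorded stress sequence is non-increasing (the iteration
    stops, keeping the previous configuration, if an update fails to
    improve).  Best of ``n_restarts`` starts is returned; the first start is
    the PCoA configuration, the rest are random.
    """
    n = d.n
    if n < k + 1:
        raise ValueError("NMDS needs at least k+1 samples")
    iu = np.triu_indices(n, 1)
    diss = d.values[iu]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)

    def run(x0: np.ndarray) -> tuple[np.ndarray, float, bool, list[float]]:
        X = x0.copy()
        prev_stress = math.inf
        converged = False
        history: list[float] = []
        for _ in range(max_iter):
            dvec = pdist(X)
            if (dvec == 0).any():
                dvec = dvec + 1e-12
            dhat = _monotone_fit(diss, dvec)
            stress = _stress1(dvec, dhat)
            if stress > prev_stress + 1e-12:
                X = prev_X
                stress = prev_stress
                break
            history.append(stress)
            if prev_stress - stress < tol:
                prev_X, prev_stress = X, stress
                converged = True
                break
            prev_X, prev_stress = X, stress
            # Guttman transform towards the fitted disparities
            ratio = np.zeros_like(dvec)
            nz = dvec > 0
            ratio[nz] = dhat[nz] / dvec[nz]
            Bmat = -squareform(ratio)
            np.fill_diagonal(Bmat, -Bmat.sum(axis=1))
            X = (Bmat @ X) / n
            X -= X.mean(axis=0)
        return prev_X, prev_stress, converged, history

    starts = []
    try:
        p = pcoa(d)
        if p.coordinates.shape[1] >= k:
            starts.append(p.coordinates[:, :k])
    except Exception:
        pass
    while len(starts) < n_restarts:
        starts.append(rng.normal(size=(n, k)))
    best = None
    for x0 in starts:
        X, stress, conv, history = run(np.asarray(x0, dtype=float))
        if best is None or stress < best[1]:
            best = (X, stress, conv, history)
    X, stress, conv, history = best
    return OrdinationResult(
        coordinates=X, ids=d.ids, stress=stress, converged=conv,
        stress_history=history,
    )


# ---------------------------------------------------------------------------
# correlation screen


def correlation_screen(
    properties: SoilProperties,
    gene_table: UnstratifiedTable,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlations between every gene (row of ``gene_table``) and
    every soil property, with two-sided p-values and a significance flag at
    ``alpha``.  Observations are pairwise-complete; cells with fewer than 3
    paired observations or a zero-variance side are flagged undefined."""
    genes = gene_table.data
    props = properties.data
    samples = [s for s in genes.columns if s in props.index]
    rows = []
    for gene in genes.index:
        x_all = genes.loc[gene, samples].to_numpy(dtype=float)
        for prop in props.columns:
            y_all = props.loc[samples, prop].to_numpy(dtype=float)
            mask = ~(np.isnan(x_all) | np.isnan(y_all))
            x, y = x_all[mask], y_all[mask]
            n = len(x)
            if n < 3 or x.std() == 0 or y.std() == 0:
                rows.append((gene, prop, np.nan, np.nan, n, False, "undefined"))
                continue
            r, p = pearsonr(x, y)
            rows.append((gene, prop, float(r), float(p), n, bool(p < alpha), ""))
    return pd.DataFrame(
        rows, columns=["gene", "property", "r", "p", "n", "significant", "note"]
    )
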