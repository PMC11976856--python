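"""Preranked gene-set enrichment, NES clustering, and over-representation.

The enrichment score walks the ranked protein list: hits increment the
running sum by ``|score| ** weight`` (normalized so hit increments total 1),
misses decrement by ``1 / (N - n_set)``; ES is the running-sum value of
maximum absolute deviation from zero.  At ``weight = 0`` this reduces to the
classic Kolmogorov-Smirnov statistic between hit and miss positions.

The permutation null draws random member labels of the same set size from
the ranked universe (a preranked analysis has no sample labels to permute).
NES divides ES by the mean magnitude of same-sign null ES; nominal p and the
FDR q follow the standard sign-stratified scheme.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named, non-empty member sets with unique names."""

    sets: Mapping[str, frozenset]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        clean = {}
        for name, members in self.sets.items():
            members = frozenset(members)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = members
        self.sets = clean

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name):
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-set enrichment statistics from a preranked run."""

    set_name: str
    es: float
    nes: float
    p: float
    fdr_q: float
    leading_edge: tuple
    n_hits: int


def compute_protein_fold_change(
    treated: pd.DataFrame, control: pd.DataFrame, min_obs: int = 1
) -> pd.DataFrame:
    """Rank proteins by mean(treated) / mean(control) abundance ratio.

    Both inputs are protein x sample tables (proteins in the index).  A
    protein is retained only when it has at least ``min_obs`` finite
    observations in each condition; dropped counts are logged.  Output is a
    two-column frame (protein, score) sorted by descending score, ties
    broken by protein id.
    """
    shared = treated.index.intersection(control.index)
    if shared.empty:
        raise ValueError("treated and control tables share no proteins")
    t = treated.loc[shared].apply(pd.to_numeric, errors="coerce")
    c = control.loc[shared].apply(pd.to_numeric, errors="coerce")
    ok = (t.notna().sum(axis=1) >= min_obs) & (c.notna().sum(axis=1) >= min_obs)
    dropped = int((~ok).sum())
    if dropped:
        logger.info("dropped %d proteins below min_obs=%d", dropped, min_obs)
    t, c = t.loc[ok], c.loc[ok]
    score = t.mean(axis=1, skipna=True) / c.mean(axis=1, skipna=True)
    out = pd.DataFrame({"protein": score.index.astype(str), "score": score.to_numpy()})
    out = out.sort_values(["score", "protein"], ascending=[False, True], kind="stable")
    return out.reset_index(drop=True)


def _as_ranked_arrays(ranked) -> tuple[np.ndarray, np.ndarray]:
    """Coerce a ranked list (DataFrame or (id, score) pairs) to arrays,
    sorted descending by score with ties broken by id."""
    if isinstance(ranked, pd.DataFrame):
        ids = ranked.iloc[:, 0].astype(str).to_numpy()
        scores = ranked.iloc[:, 1].to_numpy(dtype=float)
    else:
        ids = np.array([str(i) for i, _ in ranked])
        scores = np.array([float(s) for _, s in ranked])
    if len(ids) != len(set(ids)):
        raise ValueError("ranked list contains duplicate ids")
    order = np.lexsort((ids, -scores))
    return ids[order], scores[order]


def _running_sum(
    scores: np.ndarray, hit: np.ndarray, weight: float
) -> np.ndarray:
    """Weighted GSEA running sum over the full ranked list."""
    n = len(scores)
    n_hit = int(hit.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must hit a strict, non-empty subset of the list")
    with np.errstate(divide="ignore"):
        w = np.abs(scores) ** weight if weight != 0 else np.ones(n)
    w = np.where(np.isfinite(w), w, 0.0)
    hit_w = np.where(hit, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        raise ValueError("all hit weights are zero; cannot normalize increments")
    inc = hit_w / total
    dec = np.where(hit, 0.0, 1.0 / (n - n_hit))
    return np.cumsum(inc - dec)


def _es_from_running(running: np.ndarray) -> tuple[float, int]:
    """ES and its peak index; positive wins a magnitude tie.

    Ties are decided with a 1e-12 tolerance so the choice does not depend
    on floating-point accumulation order.
    """
    mx = float(running.max())
    mn = float(running.min())
    if max(mx, 0.0) >= max(-mn, 0.0) - 1e-12:
        es = mx if mx > 0 else 0.0
        idx = int(np.argmax(running)) if mx > 0 else 0
    else:
        es = mn
        idx = int(np.argmin(running))
    return es, idx


def enrichment_score(
    ranked, members, weight: float = 1.0
) -> tuple[float, np.ndarray, tuple]:
    """Enrichment score, running-sum profile, and leading edge for one set.

    Returns ``(es, running_sum, leading_edge)``.  The leading edge holds the
    hit members at or before the running-sum extremum (at or after it for a
    negative ES), in rank order.
    """
    ids, scores = _as_ranked_arrays(ranked)
    members = frozenset(str(m) for m in members)
    hit = np.isin(ids, list(members))
    running = _running_sum(scores, hit, weight)
    es, idx = _es_from_running(running)
    if es >= 0:
        leading = tuple(ids[: idx + 1][hit[: idx + 1]])
    else:
        leading = tuple(ids[idx:][hit[idx:]])
    return es, running, leading


def _es_only(scores: np.ndarray, hit: np.ndarray, weight: float) -> float:
    running = _running_sum(scores, hit, weight)
    return _es_from_running(running)[0]


def _null_es_for_size(
    scores: np.ndarray, size: int, weight: float, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES from random same-size member draws out of the universe."""
    n = len(scores)
    out = np.empty(n_perm)
    hit = np.zeros(n, dtype=bool)
    for i in range(n_perm):
        idx = rng.choice(n, size=size, replace=False)
        hit[:] = False
        hit[idx] = True
        out[i] = _es_only(scores, hit, weight)
    return out


def gsea_preranked(
    ranked,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection.

    For each set, the null ES distribution comes from ``n_perm`` random
    member draws of the same size (seeded and reproducible).  NES = ES /
    mean(|null ES| of matching sign); nominal p is the fraction of same-sign
    null ES at least as extreme; FDR q compares the observed NES against the
    pooled sign-matched null NES (standard scheme).  Sets with no overlap
    with the ranked universe, or larger than it, are skipped with a warning.

    Returns one row per scored set with columns
    (set, es, nes, p, fdr_q, n_hits, leading_edge).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    ids, scores = _as_ranked_arrays(ranked)
    universe = set(ids)
    n = len(ids)
    rng = np.random.default_rng(seed)

    rows = []
    null_by_set: dict[str, np.ndarray] = {}
    null_cache: dict[int, np.ndarray] = {}
    for name in sorted(sets):
        members = sets[name] & universe
        k = len(members)
        if k == 0:
            warnings.warn(f"set {name!r} has no overlap with ranked universe; skipped",
                          stacklevel=2)
            continue
        if k >= n:
            raise ValueError(f"set {name!r} covers the whole ranked universe")
        hit = np.isin(ids, list(members))
        running = _running_sum(scores, hit, weight)
        es, idx = _es_from_running(running)
        leading = tuple(ids[: idx + 1][hit[: idx + 1]]) if es >= 0 else tuple(
            ids[idx:][hit[idx:]]
        )
        if k not in null_cache:
            null_cache[k] = _null_es_for_size(scores, k, weight, n_perm, rng)
        null = null_cache[k]
        null_by_set[name] = null

        same_sign = null[null >= 0] if es >= 0 else null[null < 0]
        if len(same_sign) == 0:
            nes = np.nan
            p = np.nan
            warnings.warn(
                f"set {name!r}: no same-sign null ES; NES undefined", stacklevel=2
            )
        else:
            denom = float(np.mean(np.abs(same_sign)))
            nes = es / denom if denom > 0 else np.nan
            p = float(np.mean(np.abs(same_sign) >= abs(es)))
        rows.append(
            {
                "set": name,
                "es": es,
                "nes": nes,
                "p": p,
                "n_hits": k,
                "leading_edge": ",".join(leading),
            }
        )

    result = pd.DataFrame(rows)
    if result.empty:
        return result
    result["fdr_q"] = _gsea_fdr(result, null_by_set)
    return result[["set", "es", "nes", "p", "fdr_q", "n_hits", "leading_edge"]]


def _gsea_fdr(result: pd.DataFrame, null_by_set: Mapping[str, np.ndarray]) -> np.ndarray:
    """Sign-stratified FDR q over the pooled null NES distribution."""
    null_nes_pool = []
    for name, null in null_by_set.items():
        pos = null[null >= 0]
        neg = null[null < 0]
        mean_pos = np.mean(pos) if len(pos) else np.nan
        mean_neg = np.mean(np.abs(neg)) if len(neg) else np.nan
        norm = np.where(null >= 0, null / mean_pos, null / mean_neg)
        null_nes_pool.append(norm[np.isfinite(norm)])
    pool = np.concatenate(null_nes_pool) if null_nes_pool else np.array([])

    obs = result["nes"].to_numpy(dtype=float)
    qs = np.empty(len(obs))
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            qs[i] = np.nan
            continue
        if nes >= 0:
            n_null_sign = max(int((pool >= 0).sum()), 1)
            frac_null = (pool >= nes).sum() / n_null_sign
            n_obs_sign = max(int((obs >= 0).sum()), 1)
            frac_obs = (obs >= nes).sum() / n_obs_sign
        else:
            n_null_sign = max(int((pool < 0).sum()), 1)
            frac_null = (pool <= nes).sum() / n_null_sign
            n_obs_sign = max(int((obs < 0).sum()), 1)
            frac_obs = (obs <= nes).sum() / n_obs_sign
        qs[i] = min(frac_null / frac_obs, 1.0) if frac_obs > 0 else np.nan
    return qs


# ---------------------------------------------------------------------------
# NES-matrix hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterTree:
    """Agglomeration record for one axis: merge list, heights, leaf order."""

    labels: tuple
    merges: tuple          # ((left_cluster, right_cluster, height), ...)
    leaf_order: tuple      # label order after clustering
    newick: str


@dataclass(frozen=True)
class ClusteredMatrix:
    matrix: pd.DataFrame   # reordered copy of the input
    row_tree: "ClusterTree | None"
    col_tree: "ClusterTree | None"


def _pairwise_distance(mat: np.ndarray, labels: Sequence[str], metric: str) -> np.ndarray:
    """Pairwise-complete distance matrix; raises on undefined pairs."""
    n = mat.shape[0]
    finite = np.isfinite(mat)
    for i in range(n):
        if not finite[i].any():
            raise ValueError(f"row/column {labels[i]!r} is entirely missing")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = finite[i] & finite[j]
            needed = 2 if metric == "correlation" else 1
            if both.sum() < needed:
                raise ValueError(
                    f"items {labels[i]!r} and {labels[j]!r} share fewer than "
                    f"{needed} observed entries"
                )
            xi, xj = mat[i, both], mat[j, both]
            if metric == "correlation":
                if np.std(xi) == 0 or np.std(xj) == 0:
                    raise ValueError(
                        f"zero variance for {labels[i]!r} or {labels[j]!r} on "
                        "shared entries; correlation distance undefined"
                    )
                d[i, j] = d[j, i] = 1.0 - float(np.corrcoef(xi, xj)[0, 1])
            elif metric == "euclidean":
                d[i, j] = d[j, i] = float(
                    np.sqrt(np.mean((xi - xj) ** 2) * mat.shape[1])
                )
            else:
                raise ValueError(f"unknown distance {metric!r}")
    return d


def _agglomerate(d: np.ndarray, linkage: str) -> list[tuple[int, int, float]]:
    """Deterministic agglomeration; distance ties go to the smallest indices.

    Cluster ids: 0..n-1 are leaves, n+t is the cluster created at step t.
    Average linkage uses cluster-size weighting (UPGMA); merge heights are
    non-decreasing for both supported linkages.
    """
    if linkage not in ("average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    n = d.shape[0]
    active: dict[int, set[int]] = {i: {i} for i in range(n)}
    leaf_min: dict[int, int] = {i: i for i in range(n)}
    dist = {frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        ids = sorted(active)
        for a_i, a in enumerate(ids):
            for b in ids[a_i + 1:]:
                dd = dist[frozenset((a, b))]
                if best is None or dd < best[0] - 1e-15:
                    best = (dd, a, b)
        dd, a, b = best
        new = active[a] | active[b]
        for other in ids:
            if other in (a, b):
                continue
            da = dist[frozenset((a, other))]
            db = dist[frozenset((b, other))]
            if linkage == "average":
                na, nb = len(active[a]), len(active[b])
                dn = (na * da + nb * db) / (na + nb)
            else:
                dn = max(da, db)
            dist[frozenset((next_id, other))] = dn
        del active[a], active[b]
        active[next_id] = new
        # child holding the smallest original leaf goes first (stable layout)
        if min(leaf_min[a], leaf_min[b]) == leaf_min[b]:
            a, b = b, a
        leaf_min[next_id] = min(leaf_min[a], leaf_min[b])
        merges.append((a, b, dd))
        next_id += 1
    return merges


def _leaf_order(n: int, merges: Sequence[tuple[int, int, float]]) -> list[int]:
    children = {n + t: (a, b) for t, (a, b, _) in enumerate(merges)}

    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return walk(a) + walk(b)

    root = n + len(merges) - 1 if merges else 0
    return walk(root)


def _newick(labels: Sequence[str], merges: Sequence[tuple[int, int, float]]) -> str:
    n = len(labels)
    if not merges:
        return f"{labels[0]};"
    height = {i: 0.0 for i in range(n)}
    rep: dict[int, str] = {i: str(labels[i]) for i in range(n)}
    for t, (a, b, h) in enumerate(merges):
        la = max(h - height[a], 0.0)
        lb = max(h - height[b], 0.0)
        rep[n + t] = f"({rep[a]}:{la:g},{rep[b]}:{lb:g})"
        height[n + t] = h
    return rep[n + len(merges) - 1] + ";"


def cluster_nes(
    matrix: pd.DataFrame,
    axis: str = "both",
    distance: str = "correlation",
    linkage: str = "average",
) -> ClusteredMatrix:
    """Hierarchically cluster a condition x set NES grid.

    ``axis`` selects ``rows``, ``columns``, or ``both``.  Distances are
    pairwise-complete (missing entries excluded per pair); agglomeration is
    deterministic, with merge-distance ties resolved toward the smallest
    original indices.  Returns the reordered matrix plus, per clustered
    axis, the merge list with heights, the leaf order, and a
    nested-parenthesis (newick) rendering of the tree.
    """
    if axis not in ("rows", "columns", "both"):
        raise ValueError(f"axis must be rows/columns/both, not {axis!r}")

    def one_axis(mat: pd.DataFrame) -> ClusterTree:
        labels = list(mat.index)
        if len(labels) < 2:
            raise ValueError("need at least 2 items to cluster")
        d = _pairwise_distance(mat.to_numpy(dtype=float), labels, distance)
        merges = _agglomerate(d, linkage)
        order = _leaf_order(len(labels), merges)
        return ClusterTree(
            labels=tuple(labels),
            merges=tuple(merges),
            leaf_order=tuple(labels[i] for i in order),
            newick=_newick(labels, merges),
        )

    row_tree = col_tree = None
    out = matrix.copy()
    if axis in ("rows", "both"):
        row_tree = one_axis(out)
        out = out.loc[list(row_tree.leaf_order)]
    if axis in ("columns", "both"):
        col_tree = one_axis(out.T)
        out = out[list(col_tree.leaf_order)]
    return ClusteredMatrix(matrix=out, row_tree=row_tree, col_tree=col_tree)


# ---------------------------------------------------------------------------
# Threshold over-representation
# ---------------------------------------------------------------------------


def overrepresentation_test(
    scores: pd.DataFrame,
    pvalues: Mapping[str, float],
    sets: GeneSetCollection,
    fc_cutoff: float = 1.5,
    p_cutoff: float = 0.05,
    z_cutoff: float = 2.0,
) -> pd.DataFrame:
    """Hypergeometric over-representation of thresholded proteins per set.

    A protein is selected when its fold change is >= ``fc_cutoff`` or
    <= 1/``fc_cutoff`` *and* its p-value is below ``p_cutoff``.  Per set the
    overlap k with the selection is compared to its hypergeometric
    expectation: z = (k - E[k]) / sd(k), upper-tail hypergeometric p, and an
    ``identified`` flag when |z| >= ``z_cutoff``.  An empty selection is
    reported (k = 0 everywhere) and flagged rather than raised.
    """
    if fc_cutoff <= 0:
        raise ValueError("fc_cutoff must be positive")
    ids = scores.iloc[:, 0].astype(str).to_numpy()
    fc = scores.iloc[:, 1].to_numpy(dtype=float)
    universe = set(ids)
    n_univ = len(universe)

    pv = np.array([float(pvalues.get(i, np.nan)) for i in ids])
    extreme = (fc >= fc_cutoff) | (fc <= 1.0 / fc_cutoff)
    selected = set(ids[extreme & (pv < p_cutoff)])
    n_sel = len(selected)
    if n_sel == 0:
        warnings.warn("no proteins pass the fold-change/p cutoffs", stacklevel=2)

    rows = []
    for name in sorted(sets):
        members = sets[name] & universe
        n_set = len(members)
        if n_set == 0:
            warnings.warn(f"set {name!r} has no members in universe; skipped",
                          stacklevel=2)
            continue
        k = len(members & selected)
        expected = n_sel * n_set / n_univ
        var = (
            n_sel
            * (n_set / n_univ)
            * (1 - n_set / n_univ)
            * (n_univ - n_sel)
            / max(n_univ - 1, 1)
        )
        z = (k - expected) / np.sqrt(var) if var > 0 else 0.0
        p = float(stats.hypergeom.sf(k - 1, n_univ, n_set, n_sel)) if n_sel else 1.0
        rows.append(
            {
                "set": name,
                "overlap": k,
                "n_set": n_set,
                "n_selected": n_sel,
                "expected": expected,
                "z": z,
                "p_hypergeom": p,
                "identified": bool(abs(z) >= z_cutoff),
            }
        )
    return pd.DataFrame(rows)
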