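"""Non-metric MDS ordination and ANOSIM tests of group separation.

ANOSIM (analysis of similarities, Clarke 1993) ranks all n(n-1)/2 pairwise
dissimilarities (mid-ranks for ties) and contrasts the mean rank between
groups with the mean rank within groups:

    R = (rbar_between - rbar_within) / (M / 2),   M = n(n-1)/2

R lies in [-1, 1]; values near 1 mean all between-group dissimilarities
exceed all within-group ones.  Significance comes from permuting the group
labels — exhaustively over all distinct relabelings when that count is
within the permutation budget, otherwise by Monte-Carlo sampling with the
add-one convention p = (1 + #{R_perm >= R_obs}) / (1 + n_perm).

nMDS seeks a low-dimensional configuration whose inter-point distances
preserve the rank order of the input dissimilarities, scored by Kruskal
stress-1 computed through isotonic (pool-adjacent-violators) regression of
the configuration distances on the dissimilarity ranks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .errors import UndefinedStatisticError
from .resemblance import ResemblanceMatrix


# --------------------------------------------------------------------------
# ANOSIM
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseAnosim:
    group_a: str
    group_b: str
    r: float
    p: float
    p_bonferroni: float
    n_permutations_used: int
    exhaustive: bool


@dataclass
class AnosimResult:
    global_r: float
    global_p: float
    n_permutations_used: int
    exhaustive: bool
    pairwise: list[PairwiseAnosim] = field(default_factory=list)


def _anosim_r(rank_sq: np.ndarray, labels: np.ndarray) -> float:
    """Clarke's R from a square matrix of dissimilarity ranks."""
    n = rank_sq.shape[0]
    iu = np.triu_indices(n, k=1)
    within = labels[iu[0]] == labels[iu[1]]
    ranks = rank_sq[iu]
    m = n * (n - 1) / 2
    r_within = ranks[within].mean()
    r_between = ranks[~within].mean()
    return float((r_between - r_within) / (m / 2.0))


def _n_distinct_relabelings(counts: list[int]) -> int:
    n = sum(counts)
    total = math.factorial(n)
    for c in counts:
        total //= math.factorial(c)
    return total


def _unique_label_permutations(labels: np.ndarray):
    """All distinct arrangements of a label multiset (lexicographic)."""
    # iterative multiset-permutation generation; counts stay small because
    # this path is only taken when the total count fits the budget
    items = sorted(labels.tolist())
    n = len(items)
    perm = list(items)
    while True:
        yield np.array(perm)
        i = n - 2
        while i >= 0 and perm[i] >= perm[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while perm[j] <= perm[i]:
            j -= 1
        perm[i], perm[j] = perm[j], perm[i]
        perm[i + 1:] = reversed(perm[i + 1:])


def _anosim_one(
    d: np.ndarray,
    labels: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float, int, bool]:
    """(R, p, n_permutations_used, exhaustive) for one dissimilarity matrix."""
    n = d.shape[0]
    rank_sq = squareform(rankdata(squareform(d, checks=False)))
    r_obs = _anosim_r(rank_sq, labels)
    _, counts = np.unique(labels, return_counts=True)
    n_distinct = _n_distinct_relabelings(list(counts))
    if n_distinct <= n_perm:
        ge = sum(
            _anosim_r(rank_sq, perm) >= r_obs - 1e-12
            for perm in _unique_label_permutations(labels)
        )
        return r_obs, ge / n_distinct, n_distinct, True
    ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        if _anosim_r(rank_sq, perm) >= r_obs - 1e-12:
            ge += 1
    return r_obs, (1 + ge) / (1 + n_perm), n_perm, False


def anosim(
    resemblance: ResemblanceMatrix,
    groups: dict[str, str] | list[str],
    n_perm: int = 9999,
    rng_seed: int = 0,
    pairwise: bool = True,
) -> AnosimResult:
    """Global and pairwise ANOSIM on a resemblance matrix.

    ``groups`` maps each sample to its group (dict keyed by sample id, or a
    list aligned with ``resemblance.sample_ids``).  Needs at least two
    groups with at least two members each.  Pairwise tests re-rank the
    two-group submatrix; a pair involving a singleton group is skipped with
    a warning.
    """
    ids = resemblance.sample_ids
    if isinstance(groups, dict):
        labels = np.array([str(groups[s]) for s in ids])
    else:
        if len(groups) != len(ids):
            raise ValueError("groups length does not match samples")
        labels = np.array([str(g) for g in groups])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts >= 2).sum() < 2:
        raise UndefinedStatisticError(
            "ANOSIM needs >=2 groups with >=2 members each"
        )
    d = resemblance.dissimilarity()
    rng = np.random.default_rng([rng_seed, 0])
    r, p, used, exhaustive = _anosim_one(d, labels, n_perm, rng)
    result = AnosimResult(
        global_r=r, global_p=p, n_permutations_used=used,
        exhaustive=exhaustive,
    )
    if pairwise:
        pairs = list(combinations(sorted(uniq.tolist()), 2))
        n_tests = len(pairs)
        for k, (ga, gb) in enumerate(pairs, start=1):
            sel = np.flatnonzero((labels == ga) | (labels == gb))
            if (labels[sel] == ga).sum() < 2 or (labels[sel] == gb).sum() < 2:
                warnings.warn(
                    f"skipping pairwise ANOSIM {ga} vs {gb}: "
                    f"a group has <2 members"
                )
                continue
            sub_d = d[np.ix_(sel, sel)]
            sub_rng = np.random.default_rng([rng_seed, k])
            r2, p2, used2, ex2 = _anosim_one(
                sub_d, labels[sel], n_perm, sub_rng
            )
            result.pairwise.append(PairwiseAnosim(
                group_a=ga, group_b=gb, r=r2, p=p2,
                p_bonferroni=min(1.0, p2 * n_tests),
                n_permutations_used=used2, exhaustive=ex2,
            ))
    return result


# --------------------------------------------------------------------------
# nMDS
# --------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    sample_ids: list[str]
    coordinates: np.ndarray
    stress: float
    n_restarts: int
    converged: bool


def kruskal_stress(d: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against dissimilarities ``d``.

    Disparities are the isotonic regression of configuration distances on
    the dissimilarities (primary approach to ties);
    stress-1 = sqrt(sum (dist - dhat)^2 / sum dist^2).
    """
    iu = np.triu_indices(d.shape[0], k=1)
    diss = d[iu]
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=-1))[iu]
    order = np.argsort(diss, kind="stable")
    iso = IsotonicRegression()
    dhat = np.empty_like(dist)
    dhat[order] = iso.fit_transform(np.arange(len(order)), dist[order])
    denom = (dist ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist - dhat) ** 2).sum() / denom))


def nmds(
    resemblance: ResemblanceMatrix,
    dims: int = 2,
    n_restarts: int = 50,
    max_iter: int = 300,
    tol: float = 1e-7,
    rng_seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS by SMACOF with isotonic disparities, best of restarts.

    Restart r uses the seed stream ``[rng_seed, r]``, so increasing
    ``n_restarts`` on a fixed ``rng_seed`` re-runs the same prefix of
    initializations and the best stress is non-increasing.  The returned
    configuration is centered at the origin.
    """
    if resemblance.n_samples < 3:
        raise UndefinedStatisticError("nMDS needs >=3 samples")
    d = resemblance.dissimilarity()
    iu = np.triu_indices(d.shape[0], k=1)
    if np.allclose(d[iu], d[iu][0]):
        warnings.warn("all dissimilarities are equal; ordination is degenerate")
    best: tuple[float, np.ndarray, bool] | None = None
    for r in range(n_restarts):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords, _, n_iter = smacof(
                d, metric=False, n_components=dims, init=None, n_init=1,
                max_iter=max_iter, eps=tol,
                random_state=np.random.default_rng([rng_seed, r]).integers(2**31),
                normalized_stress=True, return_n_iter=True,
            )
        stress = kruskal_stress(d, coords)
        converged = n_iter < max_iter
        if best is None or stress < best[0]:
            best = (stress, coords, converged)
    stress, coords, converged = best
    coords = coords - coords.mean(axis=0, keepdims=True)
    return OrdinationResult(
        sample_ids=list(resemblance.sample_ids),
        coordinates=coords,
        stress=stress,
        n_restarts=n_restarts,
        converged=converged,
    )
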