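"""Hierarchical clustering with SIMPROF significance at each node.

Samples are clustered by group-average (UPGMA) agglomeration on the
dissimilarity 1 - similarity.  Each internal node is then tested with the
similarity-profile (SIMPROF) permutation test: does the group under that
node contain real multivariate structure, or could its profile of pairwise
similarities have arisen with every marker shuffled independently across
the samples?

The SIMPROF statistic is ``pi = sum_k |observed_k - mean_k|`` where
``observed`` is the ascending profile of all pairwise similarities within
the node and ``mean`` is the element-wise mean profile over datasets in
which each marker column is independently permuted across samples.  Its
null distribution comes from a second, independent batch of permuted
profiles; ``p = (1 + #{pi_perm >= pi_obs}) / (1 + n_perm_test)``, so p is
never reported as exactly zero.

Testing runs top-down from the root with the standard stopping rule: once a
node fails to reject (the group is homogeneous), none of its descendants
are tested — they inherit homogeneity.  Nodes with fewer than three samples
have at most one pairwise similarity and are untestable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as _scipy_linkage
from scipy.spatial.distance import squareform

from .errors import UndefinedStatisticError
from .resemblance import ResemblanceMatrix
from .scoring import MarkerMatrix

LINKAGES = ("average", "single", "complete")


@dataclass(frozen=True)
class SimprofAnnotation:
    """SIMPROF verdict for one dendrogram node.

    ``tested`` is False for nodes skipped by the stopping rule;
    ``testable`` is False for nodes with <3 samples.  ``significant``
    implies both.
    """

    testable: bool
    tested: bool
    significant: bool
    pi: float | None = None
    p: float | None = None


@dataclass
class Dendrogram:
    """Binary merge tree over samples, heights on the 1-similarity scale.

    Nodes use scipy numbering: leaves ``0..n-1`` in ``leaf_ids`` order,
    internal node ``n+k`` is the k-th merge.  ``merges[k] = (left, right,
    height)`` with non-decreasing heights for group-average linkage.
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int, float]]
    linkage: str = "average"
    simprof: dict[int, SimprofAnnotation] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if len(self.merges) != n - 1:
            raise ValueError(f"need {n - 1} merges for {n} leaves")

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def root(self) -> int:
        return self.n_leaves + len(self.merges) - 1

    def children(self, node: int) -> tuple[int, int]:
        left, right, _ = self.merges[node - self.n_leaves]
        return left, right

    def height(self, node: int) -> float:
        if node < self.n_leaves:
            return 0.0
        return self.merges[node - self.n_leaves][2]

    def leaves_under(self, node: int) -> list[int]:
        """Leaf indices under ``node``, in left-to-right tree order."""
        if node < self.n_leaves:
            return [node]
        left, right = self.children(node)
        return self.leaves_under(left) + self.leaves_under(right)

    def to_linkage(self) -> np.ndarray:
        """The scipy ``(n-1, 4)`` linkage array for this tree."""
        n = self.n_leaves
        sizes = {i: 1 for i in range(n)}
        z = np.zeros((n - 1, 4))
        for k, (left, right, h) in enumerate(self.merges):
            sizes[n + k] = sizes[left] + sizes[right]
            z[k] = (left, right, h, sizes[n + k])
        return z

    def cut(self, k: int) -> dict[str, int]:
        """Cut into at most ``k`` flat clusters; returns sample -> label."""
        labels = fcluster(self.to_linkage(), t=k, criterion="maxclust")
        return {s: int(lab) for s, lab in zip(self.leaf_ids, labels)}

    def node_table(self) -> list[dict]:
        """One row per internal node: members, height, SIMPROF verdict."""
        rows = []
        for k in range(len(self.merges)):
            node = self.n_leaves + k
            ann = self.simprof.get(
                node, SimprofAnnotation(testable=False, tested=False,
                                        significant=False)
            )
            rows.append({
                "node": node,
                "height": self.merges[k][2],
                "n_members": len(self.leaves_under(node)),
                "members": [self.leaf_ids[i] for i in self.leaves_under(node)],
                "testable": ann.testable,
                "tested": ann.tested,
                "significant": ann.significant,
                "pi": ann.pi,
                "p": ann.p,
            })
        return rows


def agglomerative_cluster(
    resemblance: ResemblanceMatrix, method: str = "average"
) -> Dendrogram:
    """Group-average (default) agglomeration on 1 - similarity."""
    if method not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if resemblance.n_samples < 2:
        raise UndefinedStatisticError("clustering needs >=2 samples")
    d = resemblance.dissimilarity()
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite dissimilarities")
    z = _scipy_linkage(squareform(d, checks=False), method=method)
    merges = [(int(a), int(b), float(h)) for a, b, h, _ in z]
    return Dendrogram(
        leaf_ids=list(resemblance.sample_ids), merges=merges, linkage=method
    )


def _similarity_profiles(x: np.ndarray, measure: str) -> np.ndarray:
    """Ascending pairwise-similarity profiles for a batch of sample x marker
    matrices ``x`` of shape (batch, n, m)."""
    a = x @ x.transpose(0, 2, 1)
    s = x.sum(axis=2)
    si = s[:, :, None]
    sj = s[:, None, :]
    if measure == "BRAY_CURTIS":
        denom = si + sj
        sim = np.divide(2.0 * a, denom, out=np.zeros_like(a), where=denom > 0)
    else:
        denom = si + sj - a
        sim = np.divide(a, denom, out=np.zeros_like(a), where=denom > 0)
    n = x.shape[1]
    iu = np.triu_indices(n, k=1)
    prof = sim[:, iu[0], iu[1]]
    prof.sort(axis=1)
    return prof


def _permuted_profiles(
    x: np.ndarray, n_perm: int, measure: str, rng: np.random.Generator,
    batch: int = 64,
) -> np.ndarray:
    """Profiles of datasets with every marker column independently permuted
    across samples."""
    out = []
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        tiled = np.broadcast_to(x, (b, *x.shape)).copy()
        # permuted(axis=1) shuffles along the sample axis independently for
        # every (replicate, marker) pair — exactly SIMPROF's null
        tiled = rng.permuted(tiled, axis=1)
        out.append(_similarity_profiles(tiled, measure))
        done += b
    return np.concatenate(out, axis=0)


def simprof_test(
    markers: np.ndarray | MarkerMatrix,
    n_perm_mean: int = 999,
    n_perm_test: int = 999,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = 0,
    measure: str = "BRAY_CURTIS",
) -> SimprofAnnotation:
    """SIMPROF test for internal structure within one group of samples.

    ``markers`` is markers x samples (a :class:`MarkerMatrix` or array);
    markers with any missing value are dropped before testing.
    """
    if isinstance(markers, MarkerMatrix):
        markers = markers.values
    markers = np.asarray(markers, dtype=float)
    markers = markers[~np.isnan(markers).any(axis=1)]
    n = markers.shape[1]
    if n < 3:
        return SimprofAnnotation(testable=False, tested=False,
                                 significant=False)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = markers.T.copy()  # samples x markers
    obs = _similarity_profiles(x[None, :, :], measure)[0]
    mean_prof = _permuted_profiles(x, n_perm_mean, measure, rng).mean(axis=0)
    pi_obs = float(np.abs(obs - mean_prof).sum())
    null_profs = _permuted_profiles(x, n_perm_test, measure, rng)
    pi_null = np.abs(null_profs - mean_prof).sum(axis=1)
    p = float((1 + int((pi_null >= pi_obs).sum())) / (1 + n_perm_test))
    return SimprofAnnotation(
        testable=True, tested=True, significant=bool(p < alpha),
        pi=pi_obs, p=p,
    )


def annotate_dendrogram(
    dend: Dendrogram,
    markers: MarkerMatrix,
    alpha: float = 0.05,
    rng_seed: int = 0,
    n_perm_mean: int = 999,
    n_perm_test: int = 999,
    measure: str = "BRAY_CURTIS",
) -> Dendrogram:
    """Attach a SIMPROF verdict to every internal node, top-down.

    Per-node randomness is drawn from ``default_rng([rng_seed, node])`` so
    a run is reproducible and node results do not depend on traversal
    order.  Descendants of a non-significant (or untestable) node are not
    tested and inherit homogeneity.
    """
    if list(markers.sample_ids) != list(dend.leaf_ids):
        raise ValueError("marker matrix samples do not match dendrogram leaves")
    values = markers.values
    n = dend.n_leaves
    untested = SimprofAnnotation(testable=True, tested=False,
                                 significant=False)
    for node in range(n, n + len(dend.merges)):
        leaves = dend.leaves_under(node)
        dend.simprof[node] = (
            untested if len(leaves) >= 3
            else SimprofAnnotation(testable=False, tested=False,
                                   significant=False)
        )
    stack = [dend.root]
    while stack:
        node = stack.pop()
        if node < n:
            continue
        ann = dend.simprof[node]
        if not ann.testable:
            continue
        leaves = dend.leaves_under(node)
        sub = values[:, leaves]
        result = simprof_test(
            sub, n_perm_mean=n_perm_mean, n_perm_test=n_perm_test,
            alpha=alpha, rng=np.random.default_rng([rng_seed, node]),
            measure=measure,
        )
        dend.simprof[node] = result
        if result.significant:
            stack.extend(dend.children(node))
    return dend
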