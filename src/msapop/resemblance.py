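"""Pairwise resemblance between samples from binary marker matrices.

For binary presence/absence data with pair counts a (shared presences) and
b, c (presences unique to each sample):

* Bray-Curtis similarity = 2a / (2a + b + c)  (the Sorensen coincidence —
  what "Bray-Curtis" reduces to on binary data),
* Jaccard similarity     =  a / (a + b + c).

Joint absences never contribute.  Missing marker values (NaN) are handled by
pairwise-complete deletion: a marker enters a pair's counts only when it is
observed in both samples.  Dissimilarity for clustering and ordination is
1 - similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError
from .scoring import MarkerMatrix

MEASURES = ("BRAY_CURTIS", "JACCARD")


def _abc(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int]:
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("vectors must be equal-length, 1-D, non-empty")
    a = int(((x == 1) & (y == 1)).sum())
    b = int(((x == 1) & (y == 0)).sum())
    c = int(((x == 0) & (y == 1)).sum())
    return a, b, c


def bray_curtis_similarity(
    x: np.ndarray, y: np.ndarray, zero_zero: float | None = 0.0
) -> float:
    """Binary Bray-Curtis (Sorensen) similarity 2a/(2a+b+c).

    ``zero_zero`` is returned when both vectors are all-zero; pass ``None``
    to raise instead.
    """
    a, b, c = _abc(x, y)
    denom = 2 * a + b + c
    if denom == 0:
        if zero_zero is None:
            raise UndefinedStatisticError(
                "Bray-Curtis undefined for two all-zero vectors"
            )
        return zero_zero
    return 2 * a / denom


def jaccard_similarity(
    x: np.ndarray, y: np.ndarray, zero_zero: float | None = 0.0
) -> float:
    """Jaccard similarity a/(a+b+c); joint absences ignored."""
    a, b, c = _abc(x, y)
    denom = a + b + c
    if denom == 0:
        if zero_zero is None:
            raise UndefinedStatisticError(
                "Jaccard undefined for two all-zero vectors"
            )
        return zero_zero
    return a / denom


@dataclass
class ResemblanceMatrix:
    """Symmetric pairwise similarity in [0, 1], tagged with its measure."""

    sample_ids: list[str]
    values: np.ndarray
    measure: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError(f"expected {(n, n)} matrix")
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def dissimilarity(self) -> np.ndarray:
        """1 - similarity, with an exactly-zero diagonal."""
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.sample_ids
        )

    def write_tsv(self, path: str | Path) -> None:
        out = self.to_frame().copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", lineterminator="\n")


def resemblance_matrix(
    markers: MarkerMatrix, measure: str = "BRAY_CURTIS",
    zero_zero: float = 0.0,
) -> ResemblanceMatrix:
    """All-pairs similarity from a markers x samples matrix.

    Computed with masked matrix products: for samples i, j let V be the
    observed mask, P = presence*V; then a_ij = (P V')_ij restricted to
    markers observed in both, and the per-pair presence totals follow from
    P @ V.T.  Equivalent to calling the scalar measures on every
    pairwise-complete pair of columns.
    """
    if len(markers.sample_ids) < 2:
        raise UndefinedStatisticError("resemblance needs >=2 samples")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")
    x = markers.values.T.astype(float)  # samples x markers
    valid = ~np.isnan(x)
    p = np.where(valid, x, 0.0)
    a = p @ p.T
    # s[i, j] = number of presences of i among markers observed in both i, j
    s = p @ valid.astype(float).T
    if measure == "BRAY_CURTIS":
        denom = s + s.T
        sim = np.divide(2.0 * a, denom, out=np.full_like(a, zero_zero),
                        where=denom > 0)
    else:
        denom = s + s.T - a
        sim = np.divide(a, denom, out=np.full_like(a, zero_zero),
                        where=denom > 0)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry
    return ResemblanceMatrix(
        sample_ids=list(markers.sample_ids), values=sim, measure=measure
    )
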