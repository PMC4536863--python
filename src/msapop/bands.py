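"""Band-matrix and sample-metadata containers.

An MSAP or TMD experiment digests every DNA sample twice — once with HpaII
(the "H" lane) and once with MspI (the "M" lane) — and records the presence
(1) or absence (0) of each amplified band in each lane.  The two enzymes are
isoschizomers of the CCGG site with different methylation sensitivities, so
the *pair* of lane calls at a band is what carries the methylation signal.

:class:`BandMatrix` therefore stores two aligned ``bands x samples`` arrays,
one per lane, with ``-1`` marking a missing call (a lane that could not be
scored for that sample).  Missingness is preserved exactly; it is never
coerced to absence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BandMatrixFormatError

MISSING = -1

#: Valid assay tags.  TMD (transposon methylation display) matrices must
#: name the transposable-element family the display was anchored on.
ASSAYS = ("MSAP", "TMD")


@dataclass
class BandMatrix:
    """Paired HpaII/MspI presence-absence calls for one assay.

    Parameters
    ----------
    band_ids
        Unique identifiers of the scored band sites (rows).
    sample_ids
        Unique identifiers of the samples (columns).
    h, m
        ``int8`` arrays of shape ``(n_bands, n_samples)`` with values in
        ``{0, 1, -1}``; ``-1`` means the lane call is missing.
    assay
        ``"MSAP"`` for genome-wide profiles or ``"TMD"`` for profiles of
        CCGG sites flanking a transposable-element family.
    te_family
        TE family name (e.g. ``"Veju"``, ``"Thalos"``); required for TMD.
    """

    band_ids: list[str]
    sample_ids: list[str]
    h: np.ndarray
    m: np.ndarray
    assay: str = "MSAP"
    te_family: str | None = None

    def __post_init__(self) -> None:
        self.band_ids = list(map(str, self.band_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        self.h = np.asarray(self.h, dtype=np.int8)
        self.m = np.asarray(self.m, dtype=np.int8)
        shape = (len(self.band_ids), len(self.sample_ids))
        if self.h.shape != shape or self.m.shape != shape:
            raise BandMatrixFormatError(
                f"lane arrays must have shape {shape}; "
                f"got H {self.h.shape}, M {self.m.shape}"
            )
        for name, ids in (("band", self.band_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise BandMatrixFormatError(f"duplicate {name} ids: {dupes}")
        for lane, arr in (("H", self.h), ("M", self.m)):
            bad = ~np.isin(arr, (0, 1, MISSING))
            if bad.any():
                r, c = np.argwhere(bad)[0]
                raise BandMatrixFormatError(
                    f"non-binary value {arr[r, c]} in lane {lane} at "
                    f"band {self.band_ids[r]!r}, sample {self.sample_ids[c]!r}"
                )
        if self.assay not in ASSAYS:
            raise BandMatrixFormatError(f"unknown assay {self.assay!r}")
        if self.assay == "TMD" and not self.te_family:
            raise BandMatrixFormatError("TMD matrices require te_family")

    @property
    def n_bands(self) -> int:
        return len(self.band_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def lane(self, which: str) -> np.ndarray:
        if which not in ("H", "M"):
            raise ValueError(f"lane must be 'H' or 'M', got {which!r}")
        return self.h if which == "H" else self.m

    def subset_samples(self, keep: list[str]) -> "BandMatrix":
        """Return a copy restricted to ``keep`` (in the order given)."""
        idx = [self.sample_ids.index(s) for s in keep]
        return BandMatrix(
            band_ids=list(self.band_ids),
            sample_ids=list(keep),
            h=self.h[:, idx].copy(),
            m=self.m[:, idx].copy(),
            assay=self.assay,
            te_family=self.te_family,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandMatrix):
            return NotImplemented
        return (
            self.band_ids == other.band_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.h, other.h)
            and np.array_equal(self.m, other.m)
            and self.assay == other.assay
            and self.te_family == other.te_family
        )


@dataclass
class SampleMetadata:
    """Per-sample annotations: population of origin, generation, QC flag.

    Backed by a DataFrame indexed by ``sample_id`` with columns
    ``population`` (non-empty string), ``generation`` (positive int) and
    ``excluded`` (bool).
    """

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("population", "generation", "excluded")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise BandMatrixFormatError(f"metadata missing columns: {missing}")
        if t.index.has_duplicates:
            dupes = sorted(t.index[t.index.duplicated()].unique())
            raise BandMatrixFormatError(f"duplicate sample_id rows: {dupes}")
        if (t["population"].astype(str).str.len() == 0).any():
            raise BandMatrixFormatError("empty population label")
        gen = pd.to_numeric(t["generation"], errors="raise")
        if (gen < 1).any() or (gen != gen.astype(int)).any():
            raise BandMatrixFormatError("generation must be a positive integer")
        t["generation"] = gen.astype(int)
        t["excluded"] = t["excluded"].astype(bool)
        t.index = t.index.astype(str)
        t.index.name = "sample_id"

    @classmethod
    def from_records(
        cls,
        sample_ids: list[str],
        populations: list[str],
        generation: int | list[int] = 1,
        excluded: bool | list[bool] = False,
    ) -> "SampleMetadata":
        n = len(sample_ids)
        if np.isscalar(generation):
            generation = [int(generation)] * n
        if np.isscalar(excluded):
            excluded = [bool(excluded)] * n
        table = pd.DataFrame(
            {
                "population": list(populations),
                "generation": list(generation),
                "excluded": list(excluded),
            },
            index=pd.Index(list(map(str, sample_ids)), name="sample_id"),
        )
        return cls(table)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def population_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "population"])

    def populations(self) -> list[str]:
        """Distinct population labels in first-appearance order."""
        return list(dict.fromkeys(self.table["population"]))

    def groups_for(self, sample_ids: list[str]) -> list[str]:
        return [self.population_of(s) for s in sample_ids]

    def check_covers(self, bands: BandMatrix) -> None:
        """Every sample in ``bands`` must have exactly one metadata row."""
        absent = [s for s in bands.sample_ids if s not in self.table.index]
        if absent:
            raise BandMatrixFormatError(
                f"samples without metadata: {absent[:5]}"
                + ("..." if len(absent) > 5 else "")
            )
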