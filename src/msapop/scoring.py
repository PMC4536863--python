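"""CCGG methylation scoring from paired HpaII/MspI band calls.

Both enzymes cut unmethylated CCGG.  MspI still cuts when the internal
cytosine is CG-methylated; HpaII still cuts when the external cytosine is
hemimethylated in CHG context.  Reading the two lanes of one sample at one
band therefore classifies the site:

======  ======  =======================================
H lane  M lane  state
======  ======  =======================================
1       1       UNMETHYLATED (both enzymes cut)
0       1       CG_INTERNAL (internal cytosine methylated)
1       0       CHG_HEMI (external cytosine hemimethylated)
0       0       UNINFORMATIVE (full methylation *or* fragment absence;
                the assay cannot tell the two apart)
======  ======  =======================================

A sample's methylation level is the fraction of its scored sites that are
lane-polymorphic (H != M within the individual).  By default (0,0) sites are
excluded from the denominator because they are indistinguishable from
missing fragments; set ``include_uninformative=True`` to count them as
scored-but-monomorphic for sensitivity analysis.

Two site-level filters reproduce the study design:

* genome-wide (MSAP): between-sample presence polymorphism that never shows
  within-sample H/M polymorphism looks like ordinary AFLP sequence variation
  and is excluded (``GENETIC_AFLP``);
* TE-anchored (TMD): the same band pattern instead suggests a transposition
  presence/absence polymorphism and is excluded
  (``TRANSPOSITION_NO_METH``).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .bands import MISSING, BandMatrix, SampleMetadata
from .errors import AssayMismatchError, UndefinedStatisticError


class MethylationState(IntEnum):
    UNMETHYLATED = 0
    CG_INTERNAL = 1
    CHG_HEMI = 2
    UNINFORMATIVE = 3


class SiteFilterFlag(IntEnum):
    RETAINED = 0
    GENETIC_AFLP = 1
    TRANSPOSITION_NO_METH = 2
    LOW_QUALITY = 3


def call_site(h_present: int, m_present: int) -> MethylationState | None:
    """Classify one (band, sample) cell from its two lane calls.

    Returns ``None`` when either lane call is missing; such cells drop out
    of every numerator and denominator downstream.
    """
    if h_present == MISSING or m_present == MISSING:
        return None
    key = (int(h_present), int(m_present))
    try:
        return _TRUTH_TABLE[key]
    except KeyError:
        raise ValueError(f"lane calls must be 0/1/missing, got {key}") from None


_TRUTH_TABLE = {
    (1, 1): MethylationState.UNMETHYLATED,
    (0, 1): MethylationState.CG_INTERNAL,
    (1, 0): MethylationState.CHG_HEMI,
    (0, 0): MethylationState.UNINFORMATIVE,
}


@dataclass
class MethylationCallMatrix:
    """Per-(site, sample) methylation states plus site filter flags.

    ``states`` is ``int8`` of shape ``(n_sites, n_samples)`` holding
    :class:`MethylationState` codes, with ``-1`` for missing.  ``flags``
    holds one :class:`SiteFilterFlag` per site (``RETAINED`` until a filter
    is applied).
    """

    band_ids: list[str]
    sample_ids: list[str]
    states: np.ndarray
    assay: str = "MSAP"
    te_family: str | None = None
    flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.flags is None:
            self.flags = np.full(len(self.band_ids), SiteFilterFlag.RETAINED,
                                 dtype=np.int8)
        else:
            self.flags = np.asarray(self.flags, dtype=np.int8)

    @property
    def n_sites(self) -> int:
        return len(self.band_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def column(self, sample_id: str) -> np.ndarray:
        return self.states[:, self.sample_ids.index(sample_id)]

    def retained(self) -> np.ndarray:
        """Boolean mask over sites whose flag is RETAINED."""
        return self.flags == SiteFilterFlag.RETAINED


def score_matrix(bands: BandMatrix) -> MethylationCallMatrix:
    """Vectorized truth-table scoring of a whole band matrix.

    State counts are conserved: every (site, sample) cell is exactly one of
    the four states or missing.
    """
    h, m = bands.h, bands.m
    states = np.full(h.shape, MISSING, dtype=np.int8)
    observed = (h != MISSING) & (m != MISSING)
    code = (1 - h) + 2 * (1 - m)  # (1,1)->0, (0,1)->1, (1,0)->2, (0,0)->3
    states[observed] = code[observed].astype(np.int8)
    return MethylationCallMatrix(
        band_ids=list(bands.band_ids),
        sample_ids=list(bands.sample_ids),
        states=states,
        assay=bands.assay,
        te_family=bands.te_family,
    )


@dataclass(frozen=True)
class MethylationProfile:
    """Per-sample methylation summary.

    ``level = n_methylation_polymorphic / n_scored_sites`` and
    ``n_methylation_polymorphic = n_chg + n_cg`` by construction.
    """

    sample_id: str
    n_scored_sites: int
    n_methylation_polymorphic: int
    level: float
    n_chg: int
    n_cg: int


def _state_counts(col: np.ndarray) -> tuple[int, int, int, int]:
    return (
        int((col == MethylationState.UNMETHYLATED).sum()),
        int((col == MethylationState.CG_INTERNAL).sum()),
        int((col == MethylationState.CHG_HEMI).sum()),
        int((col == MethylationState.UNINFORMATIVE).sum()),
    )


def methylation_profile(
    calls: MethylationCallMatrix,
    sample_id: str,
    include_uninformative: bool = False,
    retained_only: bool = True,
) -> MethylationProfile:
    """Summarize one sample's methylation over (by default) retained sites."""
    col = calls.column(sample_id)
    if retained_only:
        col = col[calls.retained()]
    n_u, n_cg, n_chg, n_full = _state_counts(col)
    n_poly = n_cg + n_chg
    n_scored = n_u + n_poly + (n_full if include_uninformative else 0)
    if n_scored == 0:
        raise UndefinedStatisticError(
            f"sample {sample_id!r} has no scored sites; level undefined"
        )
    return MethylationProfile(
        sample_id=sample_id,
        n_scored_sites=n_scored,
        n_methylation_polymorphic=n_poly,
        level=n_poly / n_scored,
        n_chg=n_chg,
        n_cg=n_cg,
    )


def methylation_level(
    calls: MethylationCallMatrix,
    sample_id: str,
    include_uninformative: bool = False,
) -> float:
    """Fraction of a sample's scored sites that are H/M lane-polymorphic."""
    return methylation_profile(
        calls, sample_id, include_uninformative=include_uninformative
    ).level


def context_fractions(
    calls: MethylationCallMatrix,
    sample_ids: list[str] | None = None,
    retained_only: bool = True,
) -> tuple[float, float]:
    """Pooled (CHG fraction, CG fraction) over the given samples.

    CHG methylation shows as an H-lane-only band, CG methylation as an
    M-lane-only band; the two fractions sum to 1.
    """
    if sample_ids is None:
        sample_ids = calls.sample_ids
    idx = [calls.sample_ids.index(s) for s in sample_ids]
    sub = calls.states[:, idx]
    if retained_only:
        sub = sub[calls.retained()]
    n_chg = int((sub == MethylationState.CHG_HEMI).sum())
    n_cg = int((sub == MethylationState.CG_INTERNAL).sum())
    if n_chg + n_cg == 0:
        raise UndefinedStatisticError(
            "no methylation-polymorphic calls; context fractions undefined"
        )
    return n_chg / (n_chg + n_cg), n_cg / (n_chg + n_cg)


def _no_methylation_polymorphism_sites(calls: MethylationCallMatrix) -> np.ndarray:
    """Sites where presence varies between samples but no sample is H!=M.

    With no CG/CHG call, every observed sample is (1,1) or (0,0); the site
    is flagged when both occur.  This is the shared predicate of the
    genetic-AFLP and TMD-transposition filters.
    """
    s = calls.states
    has_meth = ((s == MethylationState.CG_INTERNAL)
                | (s == MethylationState.CHG_HEMI)).any(axis=1)
    has_present = (s == MethylationState.UNMETHYLATED).any(axis=1)
    has_absent = (s == MethylationState.UNINFORMATIVE).any(axis=1)
    return ~has_meth & has_present & has_absent


def filter_genetic_sites(calls: MethylationCallMatrix) -> np.ndarray:
    """Flag MSAP sites whose variation is ordinary (genetic) AFLP polymorphism.

    A band that is present in both lanes of some samples and absent from
    both lanes of others — never differing *between* lanes of one sample —
    carries no methylation signal and is excluded as sequence-level
    variation.  Returns a per-site :class:`SiteFilterFlag` array and also
    stores it on ``calls.flags``.
    """
    flags = np.where(
        _no_methylation_polymorphism_sites(calls),
        SiteFilterFlag.GENETIC_AFLP,
        SiteFilterFlag.RETAINED,
    ).astype(np.int8)
    calls.flags = flags
    return flags


def filter_tmd_transposition(calls: MethylationCallMatrix) -> np.ndarray:
    """Flag TMD sites that look like transposition presence/absence events.

    Same band-pattern predicate as :func:`filter_genetic_sites`, but for a
    TE-anchored display the natural explanation is an insertion
    polymorphism rather than AFLP variation; only applicable to TMD data.
    """
    if calls.assay != "TMD":
        raise AssayMismatchError(
            f"transposition filter requires a TMD matrix, got {calls.assay}"
        )
    flags = np.where(
        _no_methylation_polymorphism_sites(calls),
        SiteFilterFlag.TRANSPOSITION_NO_METH,
        SiteFilterFlag.RETAINED,
    ).astype(np.int8)
    calls.flags = flags
    return flags


def filter_sites(calls: MethylationCallMatrix) -> np.ndarray:
    """Apply the assay-appropriate site filter."""
    if calls.assay == "TMD":
        return filter_tmd_transposition(calls)
    return filter_genetic_sites(calls)


def qc_exclude_samples(
    calls: MethylationCallMatrix, max_missing: float = 0.2
) -> dict[str, bool]:
    """Flag samples whose missing-call fraction exceeds ``max_missing``.

    Returns ``{sample_id: excluded}``.
    """
    frac = (calls.states == MISSING).mean(axis=0)
    return {
        s: bool(frac[j] > max_missing) for j, s in enumerate(calls.sample_ids)
    }


@dataclass
class MarkerMatrix:
    """Binary markers x samples, one marker per retained (site, lane) band.

    ``values`` is float with NaN for missing calls so that resemblance
    computations can do pairwise-complete deletion.
    """

    marker_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray


def build_marker_matrix(
    bands: BandMatrix, flags: np.ndarray | None = None
) -> MarkerMatrix:
    """Expand retained sites into per-lane binary markers.

    Each retained band site contributes two markers — its H-lane and M-lane
    presence — following the band-as-allele convention.  Markers constant
    across samples are kept.  Excluded sites contribute nothing.
    """
    if flags is None:
        flags = np.full(bands.n_bands, SiteFilterFlag.RETAINED, dtype=np.int8)
    keep = np.asarray(flags) == SiteFilterFlag.RETAINED
    if not keep.any():
        raise UndefinedStatisticError("no retained sites; marker matrix empty")
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    for i in np.flatnonzero(keep):
        for lane, arr in (("H", bands.h), ("M", bands.m)):
            marker_ids.append(f"{bands.band_ids[i]}_{lane}")
            row = arr[i].astype(float)
            row[arr[i] == MISSING] = np.nan
            rows.append(row)
    return MarkerMatrix(
        marker_ids=marker_ids,
        sample_ids=list(bands.sample_ids),
        values=np.vstack(rows),
    )


def population_mean_level(
    profiles: list[MethylationProfile], metadata: SampleMetadata
) -> dict[str, float]:
    """Arithmetic mean of member methylation levels, per population.

    Every population present in the (non-excluded) metadata must have at
    least one profiled sample; an empty population is an error naming it.
    """
    active = metadata.table[~metadata.table["excluded"]]
    by_pop: dict[str, list[float]] = {
        str(p): [] for p in dict.fromkeys(active["population"])
    }
    for prof in profiles:
        pop = metadata.population_of(prof.sample_id)
        by_pop.setdefault(pop, []).append(prof.level)
    empty = [p for p, levels in by_pop.items() if not levels]
    if empty:
        raise UndefinedStatisticError(
            f"population(s) with no retained samples: {empty}"
        )
    return {p: float(np.mean(levels)) for p, levels in by_pop.items()}
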