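"""End-to-end analysis: score -> filter -> levels -> resemblance ->
cluster+SIMPROF -> nMDS+ANOSIM -> report.

The pipeline mirrors the standard MSAP population workflow: methylation
states are called from the paired digests, low-quality samples and
non-epigenetic band sites are excluded (with per-item reasons kept for the
report), per-sample methylation levels and pooled CHG/CG context fractions
are summarized per population, and population structure is assessed twice —
by group-average clustering on Bray-Curtis similarity with SIMPROF node
significance, and by nMDS ordination plus ANOSIM on Jaccard similarity
(both measures overridable).

Everything is deterministic given the configured seed; the seed is recorded
in the report.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as _io
from .bands import BandMatrix, SampleMetadata
from .cluster import Dendrogram, agglomerative_cluster, annotate_dendrogram
from .errors import ConfigError
from .ordination import AnosimResult, OrdinationResult, anosim, nmds
from .resemblance import MEASURES, ResemblanceMatrix, resemblance_matrix
from .scoring import (
    MethylationProfile,
    SiteFilterFlag,
    build_marker_matrix,
    context_fractions,
    filter_sites,
    methylation_profile,
    population_mean_level,
    qc_exclude_samples,
    score_matrix,
)

_FLAG_REASON = {
    int(SiteFilterFlag.GENETIC_AFLP): "genetic_aflp_polymorphism",
    int(SiteFilterFlag.TRANSPOSITION_NO_METH): "transposition_no_methylation",
    int(SiteFilterFlag.LOW_QUALITY): "low_quality",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (all knobs have defaults)."""

    band_matrix: str = ""
    metadata: str = ""
    output_dir: str = "msapop_out"
    assay: str = "MSAP"
    te_family: str | None = None
    cluster_measure: str = "BRAY_CURTIS"
    test_measure: str = "JACCARD"
    alpha: float = 0.05
    max_missing: float = 0.2
    include_uninformative_in_denominator: bool = False
    simprof_n_perm_mean: int = 999
    simprof_n_perm_test: int = 999
    anosim_n_perm: int = 9999
    nmds_dims: int = 2
    nmds_restarts: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigError(f"alpha must be in (0, 1], got {self.alpha}")
        if not 0.0 <= self.max_missing <= 1.0:
            raise ConfigError("max_missing must be in [0, 1]")
        for key in ("cluster_measure", "test_measure"):
            if getattr(self, key) not in MEASURES:
                raise ConfigError(
                    f"{key} must be one of {MEASURES}, got {getattr(self, key)!r}"
                )
        if self.assay not in ("MSAP", "TMD"):
            raise ConfigError(f"assay must be MSAP or TMD, got {self.assay!r}")
        for key in ("simprof_n_perm_mean", "simprof_n_perm_test",
                    "anosim_n_perm", "nmds_dims", "nmds_restarts"):
            if getattr(self, key) < 1:
                raise ConfigError(f"{key} must be >=1")


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__)
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s): {unknown}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def write_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(asdict(config), sort_keys=True), encoding="utf-8"
    )


@dataclass
class AnalysisResult:
    """All in-memory outputs of one pipeline run."""

    config: RunConfig
    profiles: list[MethylationProfile]
    population_means: dict[str, float]
    context: tuple[float, float]
    dendrogram: Dendrogram
    cluster_resemblance: ResemblanceMatrix
    test_resemblance: ResemblanceMatrix
    anosim: AnosimResult
    ordination: OrdinationResult
    excluded_samples: dict[str, str]
    excluded_bands: dict[str, str]
    n_input_bands: int = 0
    n_input_samples: int = 0
    report: dict[str, Any] = field(default_factory=dict)


def analyze(
    bands: BandMatrix, metadata: SampleMetadata, config: RunConfig
) -> AnalysisResult:
    """Run the full analysis on in-memory inputs."""
    metadata.check_covers(bands)
    n_input_bands, n_input_samples = bands.n_bands, bands.n_samples

    # -- sample QC ---------------------------------------------------------
    calls_all = score_matrix(bands)
    qc = qc_exclude_samples(calls_all, max_missing=config.max_missing)
    excluded_samples = {
        s: "low_quality_band_pattern" for s, bad in qc.items() if bad
    }
    for s in bands.sample_ids:
        if metadata.table.loc[s, "excluded"]:
            excluded_samples.setdefault(s, "metadata_excluded")
    kept_samples = [s for s in bands.sample_ids if s not in excluded_samples]
    if len(kept_samples) < 3:
        raise ConfigError("fewer than 3 samples survive QC")
    bands = bands.subset_samples(kept_samples)

    # -- site filtering ----------------------------------------------------
    calls = score_matrix(bands)
    flags = filter_sites(calls)
    excluded_bands = {
        bands.band_ids[i]: _FLAG_REASON[int(f)]
        for i, f in enumerate(flags)
        if f != SiteFilterFlag.RETAINED
    }

    # -- levels and contexts ----------------------------------------------
    include_full = config.include_uninformative_in_denominator
    profiles = [
        methylation_profile(calls, s, include_uninformative=include_full)
        for s in kept_samples
    ]
    meta_kept = SampleMetadata(metadata.table.loc[kept_samples].copy())
    pop_means = population_mean_level(profiles, meta_kept)
    context = context_fractions(calls)

    # -- resemblance, clustering, SIMPROF ---------------------------------
    markers = build_marker_matrix(bands, flags)
    cluster_res = resemblance_matrix(markers, config.cluster_measure)
    dend = agglomerative_cluster(cluster_res)
    annotate_dendrogram(
        dend, markers,
        alpha=config.alpha,
        rng_seed=config.seed,
        n_perm_mean=config.simprof_n_perm_mean,
        n_perm_test=config.simprof_n_perm_test,
        measure=config.cluster_measure,
    )

    # -- ordination and ANOSIM --------------------------------------------
    test_res = resemblance_matrix(markers, config.test_measure)
    groups = {s: meta_kept.population_of(s) for s in kept_samples}
    anosim_result = anosim(
        test_res, groups, n_perm=config.anosim_n_perm, rng_seed=config.seed
    )
    ordination = nmds(
        test_res, dims=config.nmds_dims, n_restarts=config.nmds_restarts,
        rng_seed=config.seed,
    )

    result = AnalysisResult(
        config=config,
        profiles=profiles,
        population_means=pop_means,
        context=context,
        dendrogram=dend,
        cluster_resemblance=cluster_res,
        test_resemblance=test_res,
        anosim=anosim_result,
        ordination=ordination,
        excluded_samples=excluded_samples,
        excluded_bands=excluded_bands,
        n_input_bands=n_input_bands,
        n_input_samples=n_input_samples,
    )
    result.report = build_report(result, meta_kept)
    return result


def build_report(
    result: AnalysisResult, metadata: SampleMetadata
) -> dict[str, Any]:
    """Assemble the machine-readable report (deterministic key order)."""
    cfg = result.config
    chg_frac, cg_frac = result.context
    samples = [
        {
            "sample_id": p.sample_id,
            "population": metadata.population_of(p.sample_id),
            "n_scored_sites": p.n_scored_sites,
            "n_methylation_polymorphic": p.n_methylation_polymorphic,
            "n_chg": p.n_chg,
            "n_cg": p.n_cg,
            "level": p.level,
            "level_pct": 100.0 * p.level,
        }
        for p in result.profiles
    ]
    report: dict[str, Any] = {
        "run": {
            "assay": cfg.assay,
            "te_family": cfg.te_family,
            "seed": cfg.seed,
            "cluster_measure": cfg.cluster_measure,
            "test_measure": cfg.test_measure,
            "alpha": cfg.alpha,
        },
        "accounting": {
            "n_input_bands": result.n_input_bands,
            "n_retained_bands": result.n_input_bands
            - len(result.excluded_bands),
            "n_excluded_bands": len(result.excluded_bands),
            "n_input_samples": result.n_input_samples,
            "n_retained_samples": len(result.profiles),
            "n_excluded_samples": len(result.excluded_samples),
            "excluded_samples": [
                {"sample_id": s, "reason": r}
                for s, r in sorted(result.excluded_samples.items())
            ],
            "excluded_bands": [
                {"band_id": b, "reason": r}
                for b, r in sorted(result.excluded_bands.items())
            ],
        },
        "samples": samples,
        "population_mean_levels": {
            pop: {"level": lvl, "level_pct": 100.0 * lvl}
            for pop, lvl in result.population_means.items()
        },
        "context_fractions": {
            "chg": chg_frac,
            "cg": cg_frac,
            "chg_pct": 100.0 * chg_frac,
            "cg_pct": 100.0 * cg_frac,
        },
        "anosim": {
            "global_r": result.anosim.global_r,
            "global_p": result.anosim.global_p,
            "n_permutations_used": result.anosim.n_permutations_used,
            "exhaustive": result.anosim.exhaustive,
            "pairwise": [asdict(pw) for pw in result.anosim.pairwise],
        },
        "simprof_nodes": result.dendrogram.node_table(),
        "nmds": {
            "stress": result.ordination.stress,
            "n_restarts": result.ordination.n_restarts,
            "converged": result.ordination.converged,
            "coordinates": {
                s: [float(v) for v in xy]
                for s, xy in zip(result.ordination.sample_ids,
                                 result.ordination.coordinates)
            },
        },
    }
    return report


def run_pipeline(
    config: RunConfig,
    bands: BandMatrix | None = None,
    metadata: SampleMetadata | None = None,
) -> AnalysisResult:
    """Run the pipeline from files (or in-memory inputs) and write artifacts.

    Writes ``report.json``, ``dendrogram.nwk``, ``simprof_nodes.tsv``,
    ``anosim_pairwise.tsv`` and ``nmds_coordinates.tsv`` into
    ``config.output_dir``.
    """
    if bands is None:
        bands = _io.read_band_matrix(
            config.band_matrix, assay=config.assay, te_family=config.te_family
        )
    if metadata is None:
        metadata = _io.read_metadata(config.metadata)
    result = analyze(bands, metadata, config)

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    _io.write_report(result.report, out / "report.json")
    _io.write_newick(result.dendrogram, out / "dendrogram.nwk")

    nodes = pd.DataFrame(result.report["simprof_nodes"])
    nodes["members"] = nodes["members"].map(",".join)
    nodes.to_csv(out / "simprof_nodes.tsv", sep="\t", index=False,
                 lineterminator="\n")

    pd.DataFrame(result.report["anosim"]["pairwise"]).to_csv(
        out / "anosim_pairwise.tsv", sep="\t", index=False,
        lineterminator="\n",
    )
    coords = pd.DataFrame.from_dict(
        result.report["nmds"]["coordinates"], orient="index",
        columns=[f"axis{k + 1}" for k in range(config.nmds_dims)],
    )
    coords.index.name = "sample_id"
    coords.to_csv(out / "nmds_coordinates.tsv", sep="\t",
                  lineterminator="\n")
    return result
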