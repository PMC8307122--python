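"""End-to-end orchestration: filter -> classify -> summarize -> report.

A single :class:`RunConfig` drives the whole triage: the filter cascade
on the cohort/control VCFs, tier/level/pathway classification of the
survivors, the carrier matrix and stratified frequencies, and the
level-grouped report tables. Outputs are tab-delimited plus a JSON run
manifest; reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import cohort_stats, variant_io
from .clinical_catalog import TierCall, classify_variants
from .cohort_stats import CohortMatrix, FrequencyResult, build_matrix, frequency_table
from .filter_cascade import (
    DEFAULT_CODING_CONSEQUENCES,
    FilterConfig,
    FilterTrace,
    run_cascade,
)
from .model import AnnotatedVariant, TriageError
from .variant_io import CatalogBundle

STAGE_FILTER = "filter"
STAGE_CLASSIFY = "classify"
STAGE_SUMMARIZE = "summarize"
STAGE_REPORT = "report"


class ConfigError(TriageError):
    """Run configuration failed validation before any stage started."""


class StageError(TriageError):
    """A pipeline stage failed; carries the stage name and partial trace."""

    def __init__(self, stage: str, cause: Exception, trace: Optional[FilterTrace] = None):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.trace = trace


@dataclass
class RunConfig:
    """Validated paths and settings for one pipeline run."""

    cohort_vcfs: List[Path]
    control_vcfs: List[Path]
    population_af: Path
    mutation_census: Path
    clinical_levels: Path
    pathways: Path
    metadata: Path
    out_dir: Path
    annotation_field: str = variant_io.DEFAULT_ANNOTATION_FIELD
    filter: FilterConfig = field(default_factory=FilterConfig)
    stratify_by: Optional[str] = None
    groups: List[Tuple[str, int]] = field(default_factory=list)  # (gene, aa_pos)
    seed: int = 0

    def validate(self) -> None:
        missing = [
            str(p)
            for p in [
                *self.cohort_vcfs, *self.control_vcfs, self.population_af,
                self.mutation_census, self.clinical_levels, self.pathways, self.metadata,
            ]
            if not Path(p).exists()
        ]
        if missing:
            raise ConfigError(f"missing input path(s): {missing}")
        if not self.cohort_vcfs:
            raise ConfigError("at least one cohort VCF is required")
        self.out_dir = Path(self.out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        base = Path(path).parent

        def _p(v: str) -> Path:
            p = Path(v)
            return p if p.is_absolute() else base / p

        try:
            fconf = raw.get("filter", {})
            config = cls(
                cohort_vcfs=[_p(v) for v in raw["cohort_vcfs"]],
                control_vcfs=[_p(v) for v in raw.get("control_vcfs", [])],
                population_af=_p(raw["population_af"]),
                mutation_census=_p(raw["mutation_census"]),
                clinical_levels=_p(raw["clinical_levels"]),
                pathways=_p(raw["pathways"]),
                metadata=_p(raw["metadata"]),
                out_dir=_p(raw["out_dir"]),
                annotation_field=raw.get("annotation_field", variant_io.DEFAULT_ANNOTATION_FIELD),
                filter=FilterConfig(
                    coding_consequences=frozenset(
                        fconf.get("coding_consequences", DEFAULT_CODING_CONSEQUENCES)
                    ),
                    af_population=fconf.get("population", "LAT"),
                    af_threshold=float(fconf.get("threshold", 0.05)),
                    match_mode=fconf.get("match_mode", "allele"),
                ),
                stratify_by=raw.get("stratify_by"),
                groups=[_parse_group(g) for g in raw.get("groups", [])],
                seed=int(raw.get("seed", 0)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: invalid config: {exc}") from exc
        return config

    def canonical_dict(self) -> dict:
        return {
            "cohort_vcfs": [str(p) for p in self.cohort_vcfs],
            "control_vcfs": [str(p) for p in self.control_vcfs],
            "population_af": str(self.population_af),
            "mutation_census": str(self.mutation_census),
            "clinical_levels": str(self.clinical_levels),
            "pathways": str(self.pathways),
            "metadata": str(self.metadata),
            "annotation_field": self.annotation_field,
            "filter": {
                "coding_consequences": sorted(self.filter.coding_consequences),
                "population": self.filter.af_population,
                "threshold": self.filter.af_threshold,
                "match_mode": self.filter.match_mode,
            },
            "stratify_by": self.stratify_by,
            "groups": [f"{g}:{p}" for g, p in self.groups],
            "seed": self.seed,
        }


def _parse_group(spec: str) -> Tuple[str, int]:
    gene, _, pos = str(spec).partition(":")
    if not gene or not pos.isdigit():
        raise ValueError(f"group spec must be GENE:residue, got {spec!r}")
    return gene, int(pos)


@dataclass
class PipelineResult:
    """In-memory bundle of everything one run produced."""

    survivors: List[AnnotatedVariant]
    calls: List[TierCall]
    trace: FilterTrace
    matrix: CohortMatrix
    variant_table: pd.DataFrame
    frequencies: pd.DataFrame
    level_report: pd.DataFrame
    manifest: dict
    out_dir: Path


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def render_level_report(
    survivors: Sequence[AnnotatedVariant],
    calls: Sequence[TierCall],
    matrix: CohortMatrix,
) -> pd.DataFrame:
    """Per-level grouped variant table (the figure analogues).

    Rows are grouped by clinical level (strongest first, unleveled genes
    in a trailing residual group) then gene, one row per variant, with
    carrier counts split by new-onset/relapse status. Every classified
    variant appears in exactly one group.
    """
    status = matrix.sample_attrs.loc[matrix.samples, "status"].to_numpy()
    new_onset = status == "new-onset"
    relapse = status == "relapse"
    rows = []
    seen = set()
    for v, call in zip(survivors, calls):
        key = (v.gene, v.change_label)
        if key in seen:  # one row per variant even if read from several VCFs
            continue
        seen.add(key)
        col = matrix.column(key)
        rows.append(
            {
                "level": call.level if call.level is not None else "unleveled",
                "gene": v.gene,
                "protein_change": v.change_label,
                "tier": call.tier,
                "pathway": ";".join(call.pathways),
                "n_new_onset": int(col[new_onset].sum()),
                "n_relapse": int(col[relapse].sum()),
                "n_carriers": int(col.sum()),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["level", "gene", "protein_change", "tier", "pathway",
                 "n_new_onset", "n_relapse", "n_carriers"],
    )
    if len(df):
        order = df["level"].map(lambda v: 99 if v == "unleveled" else int(v))
        df = (
            df.assign(_o=order)
            .sort_values(["_o", "gene", "protein_change"], kind="mergesort")
            .drop(columns="_o")
            .reset_index(drop=True)
        )
    return df


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full triage and write the output bundle.

    Any stage error aborts with the failing stage's name and the
    partial filter trace; outputs are written atomically at the end, so
    a failed run leaves nothing half-written.
    """
    config.validate()
    trace: Optional[FilterTrace] = None

    try:
        catalogs = CatalogBundle.from_paths(
            config.population_af, config.mutation_census,
            config.clinical_levels, config.pathways,
        )
        metadata = cohort_stats.read_metadata(config.metadata)
        cohort = variant_io.read_vcfs(config.cohort_vcfs, config.annotation_field)
        controls = variant_io.read_vcfs(config.control_vcfs, config.annotation_field)
    except ConfigError:
        raise
    except Exception as exc:
        raise StageError(STAGE_FILTER, exc) from exc

    try:
        survivors, trace = run_cascade(cohort, controls, catalogs.population_af, config.filter)
    except Exception as exc:
        raise StageError(STAGE_FILTER, exc) from exc

    try:
        calls = classify_variants(
            survivors, catalogs.mutation_census, catalogs.clinical_levels, catalogs.pathways
        )
    except Exception as exc:
        raise StageError(STAGE_CLASSIFY, exc, trace) from exc

    try:
        matrix = build_matrix(survivors, metadata)
        freq_results: List[FrequencyResult] = []
        seen_keys = set()
        for v in survivors:
            key = (v.gene, v.change_label)
            if key in seen_keys:
                continue
            seen_keys.add(key)
            freq_results += cohort_stats.carrier_frequency(matrix, key)
            if config.stratify_by:
                freq_results += cohort_stats.carrier_frequency(matrix, key, config.stratify_by)
        for gene, aa_pos in config.groups:
            freq_results += cohort_stats.carrier_frequency(matrix, (gene, aa_pos))
            if config.stratify_by:
                freq_results += cohort_stats.carrier_frequency(
                    matrix, (gene, aa_pos), config.stratify_by
                )
        freq_df = frequency_table(freq_results)
    except Exception as exc:
        raise StageError(STAGE_SUMMARIZE, exc, trace) from exc

    try:
        level_df = render_level_report(survivors, calls, matrix)
        status_of = matrix.sample_attrs["status"].to_dict()
        var_rows = []
        for v, call in zip(survivors, calls):
            for sample in sorted(v.carriers()):
                var_rows.append(
                    {
                        "sample": sample, "gene": v.gene, "chrom": v.chrom, "pos": v.pos,
                        "ref": v.ref, "alt": v.alt, "protein_change": v.change_label,
                        "consequence": v.consequence, "tier": call.tier,
                        "level": call.level if call.level is not None else "",
                        "pathway": ";".join(call.pathways),
                        "status": status_of.get(sample, ""),
                    }
                )

        out = config.out_dir
        variant_df = variant_io.write_variant_table(var_rows, out / "variants.tsv")
        _atomic_write(out / "frequencies.tsv", freq_df.to_csv(sep="\t", index=False))
        _atomic_write(out / "level_report.tsv", level_df.to_csv(sep="\t", index=False))
        matrix_df = pd.DataFrame(
            matrix.carriers.astype(int),
            index=pd.Index(matrix.samples, name="sample"),
            columns=[f"{g} {c}" for g, c in matrix.variant_keys],
        )
        _atomic_write(out / "carrier_matrix.tsv", matrix_df.to_csv(sep="\t"))
        _atomic_write(
            out / "filter_trace.json", json.dumps(trace.as_dict(), indent=2) + "\n"
        )

        manifest = {
            "config_sha256": hashlib.sha256(
                json.dumps(config.canonical_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "catalogs": {
                "population_af": _sha256(Path(config.population_af)),
                "mutation_census": _sha256(Path(config.mutation_census)),
                "clinical_levels": _sha256(Path(config.clinical_levels)),
                "pathways": _sha256(Path(config.pathways)),
            },
            "stages": trace.as_dict(),
            "n_samples": len(matrix.samples),
            "n_classified": len(calls),
            "outputs": {
                name: _sha256(out / name)
                for name in ["variants.tsv", "frequencies.tsv", "level_report.tsv",
                             "carrier_matrix.tsv", "filter_trace.json"]
            },
        }
        _atomic_write(out / "manifest.json", json.dumps(manifest, indent=2) + "\n")
    except Exception as exc:
        raise StageError(STAGE_REPORT, exc, trace) from exc

    return PipelineResult(
        survivors=survivors, calls=calls, trace=trace, matrix=matrix,
        variant_table=variant_df, frequencies=freq_df, level_report=level_df,
        manifest=manifest, out_dir=config.out_dir,
    )
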