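"""Reading and writing VCFs, catalogue tables, and report tables.

VCF input is VCF v4.x with a pipe-delimited annotation INFO field
(default ``ANN``) carrying ``gene|consequence|protein_change``
sub-fields, one entry per alt allele — the shape emitted by VEP/SnpEff
style annotators. Catalogue inputs are tab-delimited snapshots standing
in for the population-frequency, mutation-census, clinical-level,
pathway and common-site databases the pipeline consumes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
import pysam

from .model import (
    AnnotatedVariant,
    ProteinChangeError,
    ProteinVariant,
    TriageError,
    VariantKey,
)

logger = logging.getLogger(__name__)

DEFAULT_ANNOTATION_FIELD = "ANN"


class VcfParseError(TriageError):
    """A VCF record could not be parsed."""


class CatalogError(TriageError):
    """A catalogue table failed validation."""


_PROTEIN_TOKEN = re.compile(r"^([A-Za-z])\s*(\d+)\s*(\*|fs|[A-Za-z])$")


def parse_protein_change(token: str, gene: str = "") -> ProteinVariant:
    """Parse a compact protein-change token like ``G12A``, ``C303*`` or ``K100fs``.

    Whitespace around components is tolerated (tables sometimes print
    ``C303 *``). Raises :class:`ProteinChangeError` for tokens that do
    not match ``<AA><digits><AA|*|fs>`` or violate residue validity.
    """
    m = _PROTEIN_TOKEN.match(token.strip())
    if m is None:
        raise ProteinChangeError(f"unparseable protein change token {token!r}")
    aa_ref, pos, aa_alt = m.group(1).upper(), int(m.group(2)), m.group(3)
    if aa_alt not in ("*", "fs"):
        aa_alt = aa_alt.upper()
    return ProteinVariant(gene=gene, aa_ref=aa_ref, aa_pos=pos, aa_alt=aa_alt)


def format_protein_change(pv: ProteinVariant) -> str:
    """Inverse of :func:`parse_protein_change` (up to whitespace)."""
    return str(pv)


def _dosage_from_gt(alleles: Tuple[Optional[int], ...], alt_index: int) -> Optional[int]:
    """Dosage of the alt allele with 1-based index ``alt_index`` in a GT tuple.

    A fully missing genotype maps to missing; a half call counts the
    known alleles only.
    """
    known = [a for a in alleles if a is not None]
    if not known:
        return None
    return sum(1 for a in known if a == alt_index)


def read_vcf(
    path: str | Path,
    annotation_field: str = DEFAULT_ANNOTATION_FIELD,
) -> List[AnnotatedVariant]:
    """Read a VCF into split, annotated single-alt variant records.

    One :class:`AnnotatedVariant` per (site, alt allele); multi-allelic
    records are split and annotation entries are matched to alt alleles
    by index. Records whose annotation is absent or malformed are kept
    with consequence ``"unannotated"`` (a record-level warning is
    logged). Extra annotation entries beyond one per alt are logged as
    alternates and dropped, keeping the first.
    """
    path = Path(path)
    out: List[AnnotatedVariant] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot open VCF {path}: {exc}") from exc
    with vcf:
        samples = list(vcf.header.samples)
        for lineno, rec in enumerate(vcf, start=1):
            try:
                alts = rec.alts or ()
                ann_entries: Sequence[str] = ()
                if annotation_field in rec.info:
                    raw = rec.info[annotation_field]
                    ann_entries = (raw,) if isinstance(raw, str) else tuple(raw)
                if len(ann_entries) > len(alts):
                    logger.warning(
                        "%s %s:%d: %d annotation entries for %d alt allele(s); "
                        "keeping the first per allele",
                        path.name, rec.chrom, rec.pos, len(ann_entries), len(alts),
                    )
                for i, alt in enumerate(alts):
                    gene, consequence, pc_raw = "", "unannotated", ""
                    pv: Optional[ProteinVariant] = None
                    if i < len(ann_entries):
                        parts = ann_entries[i].split("|")
                        if len(parts) != 3:
                            logger.warning(
                                "%s %s:%d alt %s: expected 3 pipe-delimited annotation "
                                "sub-fields, got %d; keeping variant as unannotated",
                                path.name, rec.chrom, rec.pos, alt, len(parts),
                            )
                        else:
                            gene, consequence, pc_raw = (p.strip() for p in parts)
                            if not consequence:
                                consequence = "unannotated"
                            if pc_raw:
                                try:
                                    pv = parse_protein_change(pc_raw, gene=gene)
                                except ProteinChangeError:
                                    logger.warning(
                                        "%s %s:%d %s: unparseable protein change %r; "
                                        "kept as raw string, excluded from tier matching",
                                        path.name, rec.chrom, rec.pos, gene, pc_raw,
                                    )
                    genotypes: Dict[str, Optional[int]] = {}
                    for s in samples:
                        gt = rec.samples[s].get("GT", (None,))
                        genotypes[s] = _dosage_from_gt(tuple(gt), i + 1)
                    out.append(
                        AnnotatedVariant(
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            gene=gene,
                            consequence=consequence,
                            protein_change=pv,
                            protein_change_raw=pc_raw,
                            sample_genotypes=genotypes,
                        )
                    )
            except VcfParseError:
                raise
            except Exception as exc:  # pragma: no cover - defensive
                raise VcfParseError(
                    f"malformed VCF record #{lineno} in {path} at {rec.chrom}:{rec.pos}: {exc}"
                ) from exc
    return out


def read_vcfs(
    paths: Iterable[str | Path],
    annotation_field: str = DEFAULT_ANNOTATION_FIELD,
) -> List[AnnotatedVariant]:
    """Read several (e.g. per-sample) VCFs and merge records sharing the
    same allele key and annotation by union of their sample genotypes."""
    return merge_variants(v for p in paths for v in read_vcf(p, annotation_field))


def merge_variants(variants: Iterable[AnnotatedVariant]) -> List[AnnotatedVariant]:
    """Merge records with identical (key, gene, consequence, change) by
    combining their per-sample dosages. Input order of first appearance
    is preserved."""
    merged: Dict[tuple, AnnotatedVariant] = {}
    for v in variants:
        k = (v.key, v.gene, v.consequence, v.change_label)
        if k in merged:
            merged[k].sample_genotypes.update(v.sample_genotypes)
        else:
            merged[k] = AnnotatedVariant(
                chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, gene=v.gene,
                consequence=v.consequence, protein_change=v.protein_change,
                protein_change_raw=v.protein_change_raw,
                sample_genotypes=dict(v.sample_genotypes),
            )
    return list(merged.values())


# --- catalogue tables -------------------------------------------------

#: required columns and duplicate-key columns per catalogue kind
CATALOG_SCHEMAS: Dict[str, Tuple[Tuple[str, ...], Tuple[str, ...]]] = {
    "population_af": (
        ("gene", "chrom", "pos", "ref", "alt", "population", "af"),
        ("chrom", "pos", "ref", "alt", "population"),
    ),
    "mutation_census": (
        ("gene", "aa_ref", "aa_pos", "aa_alt",
         "f_recurrent_driver", "f_clinvar_pathogenic", "f_dnds_selection", "cmc_label"),
        ("gene", "aa_ref", "aa_pos", "aa_alt"),
    ),
    "clinical_levels": (
        ("gene", "category", "level"),
        ("gene", "category"),
    ),
    "pathways": (
        ("gene", "pathway"),
        ("gene", "pathway"),
    ),
    "common_sites": (
        ("chrom", "pos", "ref", "alt"),
        ("chrom", "pos", "ref", "alt"),
    ),
}

_LEVEL_CATEGORIES = {"diagnostic", "prognostic", "therapeutic"}
_CMC_LABELS = {"tier1", "tier2", "tier3", "other"}


def read_catalog(path: str | Path, kind: str) -> pd.DataFrame:
    """Load and validate a tab-delimited catalogue snapshot of the given kind.

    Kinds: ``population_af`` (GnomAD-style population allele
    frequencies), ``mutation_census`` (CMC-style per-change evidence
    factors), ``clinical_levels`` (OncoKB-style gene evidence levels),
    ``pathways`` (targetable-pathway membership), ``common_sites``
    (dbSNP-common-style site list). Duplicate keys are rejected.
    """
    if kind not in CATALOG_SCHEMAS:
        raise CatalogError(f"unknown catalogue kind {kind!r}; expected one of {sorted(CATALOG_SCHEMAS)}")
    required, key_cols = CATALOG_SCHEMAS[kind]
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:
        raise CatalogError(f"cannot read catalogue {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CatalogError(f"{path}: missing required column(s) {missing} for kind {kind!r}")
    df = df[list(required)].copy()
    if "pos" in df.columns:
        df["pos"] = df["pos"].astype(int)
    if "aa_pos" in df.columns:
        df["aa_pos"] = df["aa_pos"].astype(int)
    if kind == "population_af":
        df["af"] = df["af"].astype(float)
        if ((df["af"] < 0) | (df["af"] > 1)).any():
            raise CatalogError(f"{path}: allele frequencies must lie in [0, 1]")
    if kind == "mutation_census":
        for col in ("f_recurrent_driver", "f_clinvar_pathogenic", "f_dnds_selection"):
            if not df[col].isin(["0", "1"]).all():
                raise CatalogError(f"{path}: factor flag column {col!r} must be 0 or 1")
            df[col] = df[col].astype(int).astype(bool)
        bad = set(df["cmc_label"].str.lower()) - _CMC_LABELS
        if bad:
            raise CatalogError(f"{path}: unknown cmc_label value(s) {sorted(bad)}")
        df["cmc_label"] = df["cmc_label"].str.lower()
    if kind == "clinical_levels":
        bad = set(df["category"]) - _LEVEL_CATEGORIES
        if bad:
            raise CatalogError(f"{path}: unknown evidence category value(s) {sorted(bad)}")
        df["level"] = df["level"].astype(int)
        if ((df["level"] < 1) | (df["level"] > 4)).any():
            raise CatalogError(f"{path}: clinical levels must lie in 1..4")
    dup = df.duplicated(subset=list(key_cols))
    if dup.any():
        first = df.loc[dup.idxmax(), list(key_cols)].tolist()
        raise CatalogError(f"{path}: duplicate key {first} in {kind} catalogue")
    return df.reset_index(drop=True)


@dataclass
class CatalogBundle:
    """The annotation tables the classification stages consume."""

    population_af: pd.DataFrame
    mutation_census: pd.DataFrame
    clinical_levels: pd.DataFrame
    pathways: pd.DataFrame
    common_sites: Optional[pd.DataFrame] = None

    @classmethod
    def from_paths(
        cls,
        population_af: str | Path,
        mutation_census: str | Path,
        clinical_levels: str | Path,
        pathways: str | Path,
        common_sites: Optional[str | Path] = None,
    ) -> "CatalogBundle":
        return cls(
            population_af=read_catalog(population_af, "population_af"),
            mutation_census=read_catalog(mutation_census, "mutation_census"),
            clinical_levels=read_catalog(clinical_levels, "clinical_levels"),
            pathways=read_catalog(pathways, "pathways"),
            common_sites=(read_catalog(common_sites, "common_sites")
                          if common_sites is not None else None),
        )


# --- classified variant report table ----------------------------------

VARIANT_TABLE_COLUMNS = [
    "sample", "gene", "chrom", "pos", "ref", "alt",
    "protein_change", "consequence", "tier", "level", "pathway", "status",
]


def write_variant_table(rows: Iterable[dict], path: str | Path) -> pd.DataFrame:
    """Write the per-(patient, variant) classification report.

    Each row dict supplies the :data:`VARIANT_TABLE_COLUMNS` fields.
    Rows are ordered deterministically by (gene, residue position,
    sample); an empty input yields a header-only file. Returns the
    written frame.
    """
    df = pd.DataFrame(list(rows), columns=VARIANT_TABLE_COLUMNS)
    if len(df):
        aa_pos = df["protein_change"].map(_sort_pos)
        df = (
            df.assign(_aa_pos=aa_pos)
            .sort_values(["gene", "_aa_pos", "sample", "protein_change"], kind="mergesort")
            .drop(columns="_aa_pos")
            .reset_index(drop=True)
        )
    df.to_csv(path, sep="\t", index=False)
    return df


def _sort_pos(token: object) -> int:
    try:
        return parse_protein_change(str(token)).aa_pos
    except ProteinChangeError:
        return 0


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_variant_table` output."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in VARIANT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogError(f"{path}: variant table missing column(s) {missing}")
    if len(df):
        df["pos"] = df["pos"].astype(int)
    return df
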