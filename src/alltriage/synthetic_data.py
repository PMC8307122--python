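"""Synthetic inputs: cohort/control VCFs, catalogue snapshots, panels.

Everything the pipeline consumes can be generated here, deterministic
under a seed. Two kinds of input are produced:

* random cohorts with planted and background variants plus a truth
  table saying which alleles must survive the filter cascade — used for
  end-to-end equivalence testing;
* the packaged cohort fixture: a 9-patient / 7-control bundle whose
  patient-variant assignments, sample sheet, tier/level/pathway
  catalogues and allele frequencies encode the published description of
  the borderland ALL cohort.

Genomic coordinates are synthetic placeholders (one pseudo-contig per
gene); the pipeline keys on annotation, so coordinates only need to be
internally consistent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ancestry import GenotypePanel
from .model import AA_CODES, ProteinVariant, TriageError
from .variant_io import parse_protein_change

_NUCS = "ACGT"
_AA_LIST = sorted(AA_CODES)


def _stable_int(text: str) -> int:
    """Deterministic integer from a string (stable across processes)."""
    return int.from_bytes(hashlib.md5(text.encode()).digest()[:4], "big")


def variant_coordinates(gene: str, pv: ProteinVariant) -> Tuple[str, int, str, str]:
    """Synthetic but reproducible genomic coordinates for a protein change.

    Each gene gets its own pseudo-contig; the site anchors the first
    base of the codon. Ref/alt nucleotides are a stable function of the
    change so cohort VCFs and catalogue tables always agree.
    """
    h = _stable_int(f"{gene}:{pv}")
    ref = _NUCS[h % 4]
    alt = _NUCS[(h // 4) % 3 if (h // 4) % 3 < _NUCS.index(ref) else (h // 4) % 3 + 1]
    return (f"chr_{gene}", pv.aa_pos * 3 - 2, ref, alt)


# --- plain-text VCF emission ------------------------------------------

_VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=ANN,Number=.,Type=String,Description="gene|consequence|protein_change">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)

_GT = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}


def write_sample_vcf(path: str | Path, sample: str, records: Sequence[dict]) -> None:
    """Write a single-sample VCF. Each record dict carries chrom, pos,
    ref, alt, gene, consequence, protein_change, dosage. Output is
    byte-identical for identical input (no timestamps)."""
    recs = sorted(records, key=lambda r: (r["chrom"], r["pos"], r["alt"]))
    contigs = sorted({r["chrom"] for r in recs})
    lines = [_VCF_HEADER]
    lines += [f"##contig=<ID={c}>\n" for c in contigs]
    lines.append(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
    for r in recs:
        ann = f"{r['gene']}|{r['consequence']}|{r.get('protein_change', '')}"
        lines.append(
            f"{r['chrom']}\t{r['pos']}\t.\t{r['ref']}\t{r['alt']}\t.\tPASS\t"
            f"ANN={ann}\tGT\t{_GT[r.get('dosage', 1)]}\n"
        )
    Path(path).write_text("".join(lines))


# --- random cohorts with a survival truth table -----------------------


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a random cohort with planted and background variants.

    ``planted`` entries are (sample_id, gene, protein_change_token,
    consequence); planted variants are rare, private to their sample,
    and must survive the cascade. Background variants are random coding
    changes each carried by one random patient; with probability
    ``control_share_prob`` a control also carries the allele (removing
    it at the control-subtraction stage) and with probability
    ``common_af_prob`` the allele-frequency table lists it above the 5%
    threshold (removing it at the frequency stage).
    """

    n_patients: int = 9
    n_controls: int = 7
    planted: Tuple[Tuple[str, str, str, str], ...] = ()
    n_random_variants: int = 100
    control_share_prob: float = 0.3
    common_af_prob: float = 0.3
    af_population: str = "LAT"
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.control_share_prob, self.common_af_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        samples = self.patient_ids
        if len(set(samples)) != len(samples):
            raise ValueError("sample ids must be unique")
        known = set(samples)
        for sample, gene, token, _ in self.planted:
            if sample not in known:
                raise ValueError(f"planted sample {sample!r} not among patients")
            parse_protein_change(token, gene=gene)  # validates the token

    @property
    def patient_ids(self) -> List[str]:
        return [f"P{i + 1}" for i in range(self.n_patients)]

    @property
    def control_ids(self) -> List[str]:
        return [f"C{i + 1}" for i in range(self.n_controls)]


@dataclass
class GeneratedCohort:
    """Paths and truth emitted by :func:`generate_cohort`."""

    patient_vcfs: List[Path]
    control_vcfs: List[Path]
    af_table: Path
    truth: pd.DataFrame  # one row per variant with a `survives` flag
    truth_path: Path


def generate_cohort(spec: CohortSpec, out_dir: str | Path) -> GeneratedCohort:
    """Materialize a cohort spec: per-sample VCFs, an allele-frequency
    snapshot, and the truth table of cascade survivors.

    Deterministic under ``spec.seed`` — identical specs give
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    patient_records: Dict[str, List[dict]] = {s: [] for s in spec.patient_ids}
    control_records: Dict[str, List[dict]] = {s: [] for s in spec.control_ids}
    af_rows: List[dict] = []
    truth_rows: List[dict] = []

    for sample, gene, token, consequence in spec.planted:
        pv = parse_protein_change(token, gene=gene)
        chrom, pos, ref, alt = variant_coordinates(gene, pv)
        patient_records[sample].append(
            dict(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                 consequence=consequence, protein_change=str(pv), dosage=1)
        )
        truth_rows.append(
            dict(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                 protein_change=str(pv), sample=sample, kind="planted",
                 in_controls=False, common_af=False, survives=True)
        )

    for i in range(spec.n_random_variants):
        gene = f"BG{i:05d}"
        aa_ref, aa_alt = rng.choice(_AA_LIST, size=2, replace=False)
        pv = ProteinVariant(gene=gene, aa_ref=str(aa_ref),
                            aa_pos=int(rng.integers(1, 500)), aa_alt=str(aa_alt))
        chrom, pos, ref, alt = variant_coordinates(gene, pv)
        carrier = spec.patient_ids[int(rng.integers(spec.n_patients))]
        rec = dict(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                   consequence="missense_variant", protein_change=str(pv), dosage=1)
        patient_records[carrier].append(rec)

        in_controls = bool(rng.random() < spec.control_share_prob) and spec.n_controls > 0
        if in_controls:
            ctl = spec.control_ids[int(rng.integers(spec.n_controls))]
            control_records[ctl].append(dict(rec, dosage=1))

        common = bool(rng.random() < spec.common_af_prob)
        if common:
            af = float(rng.uniform(0.06, 0.5))
            af_rows.append(dict(gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
                                population=spec.af_population, af=round(af, 6)))
        elif rng.random() < 0.5:  # half the rare alleles are catalogued, half unseen
            af = float(rng.uniform(1e-5, 0.04))
            af_rows.append(dict(gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
                                population=spec.af_population, af=round(af, 6)))
        truth_rows.append(
            dict(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                 protein_change=str(pv), sample=carrier, kind="background",
                 in_controls=in_controls, common_af=common,
                 survives=not in_controls and not common)
        )

    patient_paths, control_paths = [], []
    for s in spec.patient_ids:
        p = out_dir / f"{s}.vcf"
        write_sample_vcf(p, s, patient_records[s])
        patient_paths.append(p)
    for s in spec.control_ids:
        p = out_dir / f"{s}.vcf"
        write_sample_vcf(p, s, control_records[s])
        control_paths.append(p)

    af_cols = ["gene", "chrom", "pos", "ref", "alt", "population", "af"]
    af_df = pd.DataFrame(af_rows, columns=af_cols).sort_values(
        ["chrom", "pos", "ref", "alt"], kind="mergesort"
    )
    af_path = out_dir / "population_af.tsv"
    af_df.to_csv(af_path, sep="\t", index=False)

    truth = pd.DataFrame(
        truth_rows,
        columns=["chrom", "pos", "ref", "alt", "gene", "protein_change",
                 "sample", "kind", "in_controls", "common_af", "survives"],
    ).sort_values(["chrom", "pos", "ref", "alt"], kind="mergesort").reset_index(drop=True)
    truth_path = out_dir / "truth.tsv"
    truth.to_csv(truth_path, sep="\t", index=False)

    return GeneratedCohort(
        patient_vcfs=patient_paths, control_vcfs=control_paths,
        af_table=af_path, truth=truth, truth_path=truth_path,
    )


# --- the packaged borderland cohort fixture ---------------------------

#: Published patient-variant assignments. Changes marked placeholder are
#: synthetic stand-ins for real changes whose exact notation is not
#: printed in the text (the genes and their tiers are as published).
PLACEHOLDER_CHANGE = "A1G"

FIXTURE_ASSIGNMENTS: Tuple[Tuple[str, str, str, str], ...] = (
    ("P1", "ATM", "E2366*", "stop_gained"),
    ("P1", "DNMT3A", PLACEHOLDER_CHANGE, "missense_variant"),
    ("P1", "TET2", PLACEHOLDER_CHANGE, "missense_variant"),
    ("P1", "STAT5B", "N642H", "missense_variant"),
    ("P1", "NOTCH2", "N7S", "missense_variant"),
    ("P1", "NOTCH2", "E38K", "missense_variant"),
    ("P2", "SUZ12", PLACEHOLDER_CHANGE, "missense_variant"),
    ("P2", "NOTCH2", "C19W", "missense_variant"),
    ("P3", "WT1", "C303*", "stop_gained"),
    ("P4", "NOTCH2", "C19W", "missense_variant"),
    ("P5", "SOCS1", "L174D", "missense_variant"),
    ("P7", "ROS1", "S1109L", "missense_variant"),
    ("P7", "PTEN", PLACEHOLDER_CHANGE, "missense_variant"),
    ("P7", "NOTCH2", "C19W", "missense_variant"),
    ("P8", "KRAS", "G12A", "missense_variant"),
    ("P8", "NOTCH2", "C19W", "missense_variant"),
    ("P9", "NOTCH2", "C19W", "missense_variant"),
)

PLACEHOLDER_GENES = ("DNMT3A", "TET2", "SUZ12", "PTEN")

#: Table-1 sample sheet: status (new-onset/relapse), subtype, ethnicity.
FIXTURE_METADATA: Tuple[Tuple[str, str, str, str], ...] = (
    ("P1", "relapse", "T-ALL", "Hispanic"),
    ("P2", "relapse", "pre-T-ALL", "Hispanic"),
    ("P3", "new-onset", "pre-T-ALL", "Hispanic"),
    ("P4", "new-onset", "pre-T-ALL", "Hispanic"),
    ("P5", "relapse", "early pre-B-ALL", "Hispanic"),
    ("P6", "relapse", "early pre-B-ALL", "Hispanic"),
    ("P7", "relapse", "pre-T-ALL", "Hispanic"),
    ("P8", "new-onset", "early pre-B-ALL", "Hispanic"),
    ("P9", "new-onset", "early pre-B-ALL", "Hispanic"),
)

# census rows: gene, aa_ref, aa_pos, aa_alt, f1, f2, f3, label.
# Factor combinations are reconstructions consistent with the published
# tier of each change (exact factor values are not printed): the Tier 1
# change meets factors 1+2; Tier 3 changes meet exactly one factor;
# genes whose observed change is Tier X get a Tier 3 census entry at the
# same residue with a *different* substitution, so the observed change
# matches by position only.
_FIXTURE_CENSUS = (
    ("KRAS", "G", 12, "A", 1, 1, 0, "tier1"),
    ("ROS1", "S", 1109, "L", 0, 0, 1, "tier3"),
    ("WT1", "C", 303, "*", 0, 1, 0, "tier3"),
    ("STAT5B", "N", 642, "H", 0, 1, 0, "tier3"),
    ("NOTCH2", "C", 19, "W", 0, 0, 1, "tier3"),
    ("NOTCH2", "E", 38, "K", 0, 0, 1, "tier3"),
    ("NOTCH2", "N", 7, "K", 0, 0, 1, "tier3"),     # makes observed N7S Tier X
    ("ATM", "E", 2366, "K", 0, 1, 0, "tier3"),      # makes observed E2366* Tier X
    ("SOCS1", "L", 174, "F", 0, 0, 1, "tier3"),     # makes observed L174D Tier X
    ("DNMT3A", "A", 1, "P", 0, 0, 1, "tier3"),      # placeholder-position Tier X
    ("TET2", "A", 1, "P", 0, 0, 1, "tier3"),
    ("SUZ12", "A", 1, "P", 0, 0, 1, "tier3"),
    ("PTEN", "A", 1, "P", 0, 0, 1, "tier3"),
)

_FIXTURE_LEVELS = (
    ("ROS1", "therapeutic", 1),
    ("ATM", "therapeutic", 1),
    ("KRAS", "therapeutic", 1),
    ("DNMT3A", "diagnostic", 2),
    ("DNMT3A", "prognostic", 2),
    ("TET2", "diagnostic", 2),
    ("WT1", "diagnostic", 2),
    ("STAT5B", "diagnostic", 3),
    ("SUZ12", "diagnostic", 3),
    ("PTEN", "diagnostic", 3),
    ("NOTCH2", "diagnostic", 3),
    ("SOCS1", "diagnostic", 3),
)

_FIXTURE_PATHWAYS = (
    ("KRAS", "MAPK"),
    ("ROS1", "RTK"),
    ("ATM", "DNA damage response"),
    ("STAT5B", "JAK/STAT"),
    ("SOCS1", "JAK/STAT"),
    ("DNMT3A", "epigenetic/chromatin remodeling"),
    ("TET2", "epigenetic/chromatin remodeling"),
    ("WT1", "epigenetic/chromatin remodeling"),
    ("SUZ12", "epigenetic/chromatin remodeling"),
    ("PTEN", "PI3K"),
    ("NOTCH2", "NOTCH"),
)

# decoy variants exercising each cascade stage (present in every patient)
_DECOYS = (
    # gene, token, consequence, fate
    ("DECOYCTL", "A5T", "missense_variant", "removed: carried by controls"),
    ("DECOYCOM", "T7M", "missense_variant", "removed: population AF 0.20 > 0.05"),
    ("DECOYNC", "", "intron_variant", "removed: non-coding consequence"),
    ("DECOYEQ", "G9R", "missense_variant", "kept: population AF exactly 0.05"),
)


@dataclass
class BorderlandFixture:
    """Paths of the materialized borderland cohort bundle."""

    patient_vcfs: List[Path]
    control_vcfs: List[Path]
    metadata: Path
    population_af: Path
    mutation_census: Path
    clinical_levels: Path
    pathways: Path
    common_sites: Path
    manifest: Path
    run_config: Path
    assignments: Tuple[Tuple[str, str, str, str], ...] = FIXTURE_ASSIGNMENTS


def borderland_fixture(out_dir: str | Path) -> BorderlandFixture:
    """Write the 9-patient / 7-control borderland bundle.

    Patient VCFs carry the published per-patient variant assignments
    plus decoy variants that each cascade stage must remove (one allele
    shared with controls, one above the 5% population frequency, one
    non-coding) and one boundary allele at exactly 5% that must survive.
    The catalogue snapshots encode the published tiers, levels and
    pathways; the sample sheet reproduces the published status, subtype
    and ethnicity. Fully deterministic — no randomness on this path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def _decoy_record(gene: str, token: str, consequence: str) -> dict:
        if token:
            pv = parse_protein_change(token, gene=gene)
            chrom, pos, ref, alt = variant_coordinates(gene, pv)
            return dict(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                        consequence=consequence, protein_change=str(pv), dosage=1)
        h = _stable_int(f"{gene}:nc")
        ref = _NUCS[h % 4]
        alt = _NUCS[(h + 1) % 4] if _NUCS[(h + 1) % 4] != ref else _NUCS[(h + 2) % 4]
        return dict(chrom=f"chr_{gene}", pos=100, ref=ref, alt=alt, gene=gene,
                    consequence=consequence, protein_change="", dosage=1)

    decoy_records = [_decoy_record(g, t, c) for g, t, c, _ in _DECOYS]

    patients = [m[0] for m in FIXTURE_METADATA]
    patient_paths = []
    for sample in patients:
        records = [
            _planted_record(gene, token, consequence)
            for s, gene, token, consequence in FIXTURE_ASSIGNMENTS
            if s == sample
        ]
        records += [dict(r) for r in decoy_records]
        p = out_dir / f"{sample}.vcf"
        write_sample_vcf(p, sample, records)
        patient_paths.append(p)

    control_paths = []
    ctl_record = dict(decoy_records[0])  # the control-shared decoy
    for i in range(7):
        sample = f"C{i + 1}"
        p = out_dir / f"{sample}.vcf"
        write_sample_vcf(p, sample, [dict(ctl_record)])
        control_paths.append(p)

    meta_path = out_dir / "metadata.tsv"
    pd.DataFrame(FIXTURE_METADATA, columns=["sample", "status", "subtype", "ethnicity"]).to_csv(
        meta_path, sep="\t", index=False
    )

    # population allele frequencies (Latino/Admixed American stratum):
    # planted changes are rare; decoys straddle the 5% threshold.
    af_rows = []

    def _af_row(gene: str, token: str, af: float) -> None:
        pv = parse_protein_change(token, gene=gene)
        chrom, pos, ref, alt = variant_coordinates(gene, pv)
        af_rows.append(dict(gene=gene, chrom=chrom, pos=pos, ref=ref, alt=alt,
                            population="LAT", af=af))

    _af_row("ROS1", "S1109L", 0.00016)  # published Latino/Admixed frequency 0.016%
    _af_row("KRAS", "G12A", 0.0001)
    _af_row("STAT5B", "N642H", 0.0001)
    _af_row("NOTCH2", "C19W", 0.001)
    _af_row("DECOYCOM", "T7M", 0.20)
    _af_row("DECOYEQ", "G9R", 0.05)
    af_path = out_dir / "population_af.tsv"
    pd.DataFrame(af_rows).to_csv(af_path, sep="\t", index=False)

    census_path = out_dir / "mutation_census.tsv"
    pd.DataFrame(
        _FIXTURE_CENSUS,
        columns=["gene", "aa_ref", "aa_pos", "aa_alt", "f_recurrent_driver",
                 "f_clinvar_pathogenic", "f_dnds_selection", "cmc_label"],
    ).to_csv(census_path, sep="\t", index=False)

    levels_path = out_dir / "clinical_levels.tsv"
    pd.DataFrame(_FIXTURE_LEVELS, columns=["gene", "category", "level"]).to_csv(
        levels_path, sep="\t", index=False
    )

    pathways_path = out_dir / "pathways.tsv"
    pd.DataFrame(_FIXTURE_PATHWAYS, columns=["gene", "pathway"]).to_csv(
        pathways_path, sep="\t", index=False
    )

    # a small common-sites list (the decoy sites), for interface parity
    common_rows = [
        {k: r[k] for k in ("chrom", "pos", "ref", "alt")} for r in decoy_records
    ]
    common_path = out_dir / "common_sites.tsv"
    pd.DataFrame(common_rows).to_csv(common_path, sep="\t", index=False)

    manifest_path = out_dir / "fixture_manifest.json"
    manifest = {
        "description": (
            "Synthetic borderland ALL cohort fixture: 9 patients, 7 controls, "
            "catalogue snapshots encoding the published tier/level/pathway calls."
        ),
        "reconstructions": {
            "placeholder_changes": {
                g: PLACEHOLDER_CHANGE for g in PLACEHOLDER_GENES
            },
            "notes": [
                "Placeholder changes stand in for real changes whose exact "
                "notation is not printed; they are excluded from exact-change checks.",
                "ATM E2366* is reconstructed from the published 'E2366 *' notation.",
                "Census factor combinations are reconstructions consistent with "
                "the published tiers, not measured factor values.",
            ],
        },
        "decoys": [
            {"gene": g, "protein_change": t, "consequence": c, "fate": fate}
            for g, t, c, fate in _DECOYS
        ],
    }
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")

    # ready-to-run pipeline config (paths relative to the bundle dir)
    config_path = out_dir / "config.yaml"
    config_path.write_text(
        "\n".join(
            [
                "cohort_vcfs:",
                *[f"  - {p.name}" for p in patient_paths],
                "control_vcfs:",
                *[f"  - {p.name}" for p in control_paths],
                "population_af: population_af.tsv",
                "mutation_census: mutation_census.tsv",
                "clinical_levels: clinical_levels.tsv",
                "pathways: pathways.tsv",
                "metadata: metadata.tsv",
                "out_dir: out",
                "stratify_by: status",
                "groups:",
                "  - KRAS:12",
                "",
            ]
        )
    )

    return BorderlandFixture(
        patient_vcfs=patient_paths, control_vcfs=control_paths, metadata=meta_path,
        population_af=af_path, mutation_census=census_path,
        clinical_levels=levels_path, pathways=pathways_path,
        common_sites=common_path, manifest=manifest_path, run_config=config_path,
    )


def _planted_record(gene: str, token: str, consequence: str) -> dict:
    pv = parse_protein_change(token, gene=gene)
    chrom, pos, ref, alt = variant_coordinates(gene, pv)
    return dict(chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                consequence=consequence, protein_change=str(pv), dosage=1)


# --- reference genotype panels ----------------------------------------


@dataclass(frozen=True)
class PopulationSpec:
    """One population in a synthetic panel.

    Exactly one of ``freqs`` / ``divergence`` / ``like`` describes its
    allele frequencies: an explicit per-locus vector; a divergence
    parameter (populations with divergence d are offset +-d/2 from a
    shared per-locus base frequency, alternating sign by order, so two
    such populations sit a gap of d apart); or the label of another
    population to draw from (used for unlabeled query samples).
    ``label=None`` marks samples as queries for population assignment.
    """

    label: Optional[str]
    n_samples: int
    freqs: Optional[Tuple[float, ...]] = None
    divergence: Optional[float] = None
    like: Optional[str] = None


@dataclass(frozen=True)
class PanelSpec:
    """Recipe for a synthetic reference genotype panel."""

    populations: Tuple[PopulationSpec, ...]
    n_loci: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        for pop in self.populations:
            if pop.freqs is not None:
                if len(pop.freqs) != self.n_loci:
                    raise ValueError(f"frequency vector length != n_loci for {pop.label!r}")
                if any(not (0.0 <= f <= 1.0) for f in pop.freqs):
                    raise ValueError("allele frequencies must lie in [0, 1]")


def generate_reference_panel(spec: PanelSpec) -> GenotypePanel:
    """Draw a panel: per-locus dosages are Binomial(2, f) per population.

    Deterministic under ``spec.seed``. Loci live on one pseudo-contig
    with A>G alleles; real panels are ingested through the same
    :class:`~alltriage.ancestry.GenotypePanel` format.
    """
    rng = np.random.default_rng(spec.seed)
    base = rng.uniform(0.3, 0.7, spec.n_loci)
    freqs_by_pop: Dict[str, np.ndarray] = {}
    n_divergent = 0
    resolved: List[Tuple[PopulationSpec, np.ndarray]] = []
    for pop in spec.populations:
        if pop.freqs is not None:
            f = np.asarray(pop.freqs, dtype=float)
        elif pop.divergence is not None:
            sign = 1.0 if n_divergent % 2 else -1.0
            n_divergent += 1
            f = np.clip(base + sign * pop.divergence / 2.0, 0.01, 0.99)
        elif pop.like is not None:
            if pop.like not in freqs_by_pop:
                raise TriageError(f"population {pop.like!r} referenced before definition")
            f = freqs_by_pop[pop.like]
        else:
            f = base
        if pop.label is not None:
            freqs_by_pop[pop.label] = f
        resolved.append((pop, f))

    samples, populations, rows = [], [], []
    counter = 0
    for pop, f in resolved:
        for _ in range(pop.n_samples):
            counter += 1
            tag = pop.label if pop.label is not None else "Q"
            samples.append(f"{tag}{counter:03d}")
            populations.append(pop.label)
            rows.append(rng.binomial(2, f).astype(float))
    loci = [("chr_panel", 100 + 10 * j, "A", "G") for j in range(spec.n_loci)]
    return GenotypePanel(
        samples=samples, populations=populations, loci=loci,
        dosages=np.vstack(rows) if rows else np.zeros((0, spec.n_loci)),
    )
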