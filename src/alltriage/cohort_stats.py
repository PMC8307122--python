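"""Carrier matrices, position aggregation, and stratified frequencies.

Frequencies here are carrier frequencies — the fraction of individuals
in a stratum with dosage >= 1 of a variant — not allele frequencies,
matching how small-cohort variant counts are reported ("one of nine
cases"). Position aggregation collapses all amino-acid changes at one
residue (e.g. every substitution at KRAS codon 12, "G12X") into a
single carrier group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .model import AnnotatedVariant, TriageError

logger = logging.getLogger(__name__)

#: variant key used in the matrix: (gene, protein-change label)
MatrixKey = Tuple[str, str]
#: a position group is addressed as (gene, residue position)
GroupKey = Tuple[str, int]

METADATA_COLUMNS = ["sample", "status", "subtype", "ethnicity"]


def read_metadata(path) -> pd.DataFrame:
    """Read the tab-delimited sample sheet (sample, status, subtype, ethnicity)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise TriageError(f"{path}: metadata missing column(s) {missing}")
    if df["sample"].duplicated().any():
        raise TriageError(f"{path}: duplicate sample ids in metadata")
    return df


@dataclass
class CohortMatrix:
    """Samples x variant-keys boolean carrier matrix with sample strata.

    Samples come from the metadata sheet, so individuals with no
    surviving variant are present as all-false rows and every
    denominator counts the full cohort.
    """

    samples: List[str]
    sample_attrs: pd.DataFrame  # indexed by sample; status/subtype/ethnicity
    variant_keys: List[MatrixKey]
    carriers: np.ndarray  # bool, shape (n_samples, n_keys)
    aa_positions: Dict[MatrixKey, Optional[GroupKey]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.carriers.shape != (len(self.samples), len(self.variant_keys)):
            raise TriageError("carrier matrix dimensions do not match sample/key lists")

    def column(self, key: MatrixKey) -> np.ndarray:
        try:
            j = self.variant_keys.index(key)
        except ValueError:
            raise TriageError(f"unknown variant key {key!r}") from None
        return self.carriers[:, j]

    def carrier_count(self, key: MatrixKey) -> int:
        return int(self.column(key).sum())


def build_matrix(
    variants: Sequence[AnnotatedVariant],
    metadata: pd.DataFrame,
) -> CohortMatrix:
    """Build the carrier matrix from (filtered, classified) variants.

    A sample carries a key iff its dosage of any underlying allele is
    >= 1. Raises when the VCFs mention samples absent from the metadata.
    """
    samples = metadata["sample"].tolist()
    sample_set = set(samples)
    unknown = sorted(
        {s for v in variants for s in v.sample_genotypes} - sample_set
    )
    if unknown:
        raise TriageError(f"sample id(s) in VCF but not in metadata: {unknown}")

    keys: List[MatrixKey] = []
    aa_positions: Dict[MatrixKey, Optional[GroupKey]] = {}
    cols: Dict[MatrixKey, np.ndarray] = {}
    sample_index = {s: i for i, s in enumerate(samples)}
    for v in variants:
        key = (v.gene, v.change_label)
        if key not in cols:
            keys.append(key)
            cols[key] = np.zeros(len(samples), dtype=bool)
            aa_positions[key] = (
                (v.gene, v.protein_change.aa_pos) if v.protein_change is not None else None
            )
        for s in v.carriers():
            cols[key][sample_index[s]] = True

    carriers = (
        np.column_stack([cols[k] for k in keys])
        if keys else np.zeros((len(samples), 0), dtype=bool)
    )
    attrs = metadata.set_index("sample")
    return CohortMatrix(
        samples=samples, sample_attrs=attrs, variant_keys=keys,
        carriers=carriers, aa_positions=aa_positions,
    )


def aggregate_position(matrix: CohortMatrix, gene: str, aa_pos: int) -> Tuple[str, np.ndarray]:
    """Carrier column for the group of ALL changes at one residue.

    Returns the group label (e.g. ``"KRAS G12X"``) and a boolean vector:
    a sample carries the group iff it carries any member change.
    Nonsense and frameshift changes at the position are included.
    """
    member_cols = [
        matrix.column(k)
        for k, gp in matrix.aa_positions.items()
        if gp == (gene, aa_pos)
    ]
    refs = {
        k[1][0]
        for k, gp in matrix.aa_positions.items()
        if gp == (gene, aa_pos) and k[1]
    }
    ref = refs.pop() if len(refs) == 1 else ""
    label = f"{gene} {ref}{aa_pos}X"
    if not member_cols:
        return label, np.zeros(len(matrix.samples), dtype=bool)
    return label, np.logical_or.reduce(member_cols)


@dataclass(frozen=True)
class FrequencyResult:
    """Carrier count and percentage for one key in one stratum."""

    key: str
    stratum: str
    n_carriers: int
    n_total: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_carriers <= self.n_total):
            raise TriageError(
                f"invalid counts for {self.key}/{self.stratum}: "
                f"{self.n_carriers}/{self.n_total}"
            )

    @property
    def percent(self) -> float:
        return 100.0 * self.n_carriers / self.n_total if self.n_total else math.nan


def carrier_frequency(
    matrix: CohortMatrix,
    key: Union[MatrixKey, GroupKey, np.ndarray],
    stratify_by: Optional[str] = None,
    label: Optional[str] = None,
) -> List[FrequencyResult]:
    """Per-stratum carrier frequency of a variant key, a (gene, residue)
    position group, or an explicit carrier column.

    With ``stratify_by=None`` a single pooled stratum ``"all"`` is
    returned. Strata that would have zero individuals cannot occur
    (strata are read off the sample sheet), but samples with a missing
    stratum value are dropped with a warning.
    """
    if isinstance(key, np.ndarray):
        col, name = key.astype(bool), (label or "custom")
    elif isinstance(key, tuple) and len(key) == 2 and isinstance(key[1], int):
        name, col = aggregate_position(matrix, key[0], key[1])
    else:
        col, name = matrix.column(key), f"{key[0]} {key[1]}"

    if stratify_by is None:
        return [FrequencyResult(name, "all", int(col.sum()), len(matrix.samples))]
    if stratify_by not in matrix.sample_attrs.columns:
        raise TriageError(f"unknown stratification attribute {stratify_by!r}")
    values = matrix.sample_attrs.loc[matrix.samples, stratify_by]
    defined = values.notna().to_numpy()
    if not defined.all():
        logger.warning(
            "dropping %d sample(s) with undefined %r from stratified counts",
            int((~defined).sum()), stratify_by,
        )
    out = []
    for stratum in sorted(values[defined].unique()):
        mask = (values == stratum).to_numpy() & defined
        out.append(FrequencyResult(name, str(stratum), int(col[mask].sum()), int(mask.sum())))
    return out


@dataclass(frozen=True)
class StrataComparison:
    """Fold difference in carrier percent between two strata, with the
    raw 2x2 counts for any downstream testing."""

    key: str
    stratum_a: str
    stratum_b: str
    percent_a: float
    percent_b: float
    fold: Optional[float]  # None when percent_b == 0 (undefined)
    counts: pd.DataFrame  # 2x2: carriers/non-carriers x strata


def compare_strata(results: Sequence[FrequencyResult]) -> StrataComparison:
    """Compare exactly two strata of one key: fold = percent_a / percent_b.

    A zero denominator flags the fold as undefined (None) rather than
    raising. No hypothesis test is attached — only descriptive
    percentages and the 2x2 counts are returned.
    """
    if len(results) != 2:
        raise TriageError(f"expected exactly two strata, got {len(results)}")
    a, b = results
    if a.key != b.key:
        raise TriageError(f"strata compare different keys: {a.key!r} vs {b.key!r}")
    if a.n_total < 1 or b.n_total < 1:
        raise TriageError("both strata need n_total >= 1")
    fold = (a.percent / b.percent) if b.percent > 0 else None
    counts = pd.DataFrame(
        {
            a.stratum: [a.n_carriers, a.n_total - a.n_carriers],
            b.stratum: [b.n_carriers, b.n_total - b.n_carriers],
        },
        index=["carriers", "non_carriers"],
    )
    return StrataComparison(
        key=a.key, stratum_a=a.stratum, stratum_b=b.stratum,
        percent_a=a.percent, percent_b=b.percent, fold=fold, counts=counts,
    )


def load_external_frequencies(path) -> List[FrequencyResult]:
    """Load stratified carrier counts computed on an external cohort.

    The comparison cohort used for context here (TARGET-ALL Phase II,
    dbGaP accession phs000218) is controlled-access, so its genotypes
    cannot ship with the package; users with approved access provide a
    tab-delimited table (key, stratum, n_carriers, n_total) computed on
    their side, which feeds :func:`compare_strata` unchanged.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["key", "stratum", "n_carriers", "n_total"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TriageError(f"{path}: external frequency table missing column(s) {missing}")
    return [
        FrequencyResult(str(r.key), str(r.stratum), int(r.n_carriers), int(r.n_total))
        for r in df.itertuples(index=False)
    ]


def frequency_table(results: Sequence[FrequencyResult]) -> pd.DataFrame:
    """Flatten frequency results into a report DataFrame."""
    return pd.DataFrame(
        [
            {
                "key": r.key, "stratum": r.stratum,
                "n_carriers": r.n_carriers, "n_total": r.n_total,
                "percent": round(r.percent, 4) if r.n_total else float("nan"),
            }
            for r in results
        ],
        columns=["key", "stratum", "n_carriers", "n_total", "percent"],
    )
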