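"""The variant-reduction cascade.

Without matched healthy tissue, somatic and germline variants cannot be
separated directly; the cascade instead (1) restricts to coding
consequences, (2) removes any allele carried by a healthy control, and
(3) removes alleles common (>5% by default) in the matched reference
population. The survivors are enriched for somatic mutations while rare
germline variants are deliberately retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .model import AnnotatedVariant, TriageError

#: Consequence terms treated as coding/non-synonymous by default:
#: amino-acid-changing substitutions plus the standard truncating classes.
DEFAULT_CODING_CONSEQUENCES = frozenset(
    {
        "missense_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "inframe_insertion",
        "inframe_deletion",
        "frameshift_variant",
        "splice_acceptor_variant",
        "splice_donor_variant",
    }
)

DEFAULT_POPULATION = "LAT"
DEFAULT_AF_THRESHOLD = 0.05


@dataclass(frozen=True)
class FilterConfig:
    """Settings for the three-stage cascade.

    ``match_mode`` controls how cohort variants are matched against
    controls and the frequency catalogue: ``"allele"`` requires the
    identical (chrom, pos, ref, alt) key; ``"position"`` matches any
    allele at the same (chrom, pos).
    """

    coding_consequences: frozenset = DEFAULT_CODING_CONSEQUENCES
    af_population: str = DEFAULT_POPULATION
    af_threshold: float = DEFAULT_AF_THRESHOLD
    match_mode: str = "allele"

    def __post_init__(self) -> None:
        if not (0 < self.af_threshold < 1):
            raise ValueError(f"af_threshold must lie in (0, 1), got {self.af_threshold}")
        if not self.coding_consequences:
            raise ValueError("coding_consequences must be non-empty")
        if self.match_mode not in ("allele", "position"):
            raise ValueError(f"match_mode must be 'allele' or 'position', got {self.match_mode!r}")


@dataclass
class FilterTrace:
    """Per-stage audit counts; stages chain (n_out of k == n_in of k+1)."""

    stages: List[Tuple[str, int, int, int]] = field(default_factory=list)

    def record(self, name: str, n_in: int, n_out: int) -> None:
        if self.stages and self.stages[-1][3] != n_in:
            raise TriageError(
                f"trace chaining broken at stage {name!r}: previous n_out "
                f"{self.stages[-1][3]} != n_in {n_in}"
            )
        self.stages.append((name, n_in, n_in - n_out, n_out))

    def as_dict(self) -> Dict[str, Dict[str, int]]:
        return {
            name: {"n_in": n_in, "n_removed": n_rm, "n_out": n_out}
            for name, n_in, n_rm, n_out in self.stages
        }

    @property
    def final_count(self) -> int:
        return self.stages[-1][3] if self.stages else 0


def restrict_coding(
    variants: Sequence[AnnotatedVariant],
    coding_consequences: frozenset = DEFAULT_CODING_CONSEQUENCES,
) -> List[AnnotatedVariant]:
    """Keep variants whose consequence is in the coding set.

    Unannotated variants fail the membership test and are removed."""
    return [v for v in variants if v.consequence in coding_consequences]


def _control_keys(controls: Iterable[AnnotatedVariant], match_mode: str) -> set:
    keys = set()
    for v in controls:
        if any(d is not None and d >= 1 for d in v.sample_genotypes.values()):
            keys.add(v.key if match_mode == "allele" else v.position_key)
    return keys


def subtract_controls(
    cohort_variants: Sequence[AnnotatedVariant],
    control_variants: Sequence[AnnotatedVariant],
    match_mode: str = "allele",
) -> List[AnnotatedVariant]:
    """Remove cohort variants carried (dosage >= 1) by ANY control sample."""
    seen = _control_keys(control_variants, match_mode)
    if match_mode == "allele":
        return [v for v in cohort_variants if v.key not in seen]
    return [v for v in cohort_variants if v.position_key not in seen]


def _af_lookup(af_catalog: pd.DataFrame, population: str, match_mode: str) -> Dict[tuple, float]:
    sub = af_catalog[af_catalog["population"] == population]
    if match_mode == "allele":
        return {
            (r.chrom, r.pos, r.ref, r.alt): r.af
            for r in sub.itertuples(index=False)
        }
    # position mode: a position is as common as its most common allele
    out: Dict[tuple, float] = {}
    for r in sub.itertuples(index=False):
        k = (r.chrom, r.pos)
        out[k] = max(out.get(k, 0.0), r.af)
    return out


def filter_population_af(
    variants: Sequence[AnnotatedVariant],
    af_catalog: pd.DataFrame,
    population: str = DEFAULT_POPULATION,
    threshold: float = DEFAULT_AF_THRESHOLD,
    match_mode: str = "allele",
) -> List[AnnotatedVariant]:
    """Remove variants with catalogue frequency strictly above the threshold.

    The comparison is strict ("more than 5%"): a frequency equal to the
    threshold survives. Variants absent from the catalogue are kept —
    absence is treated as rarity, so rare germline variants the
    catalogue has never seen are retained.
    """
    lookup = _af_lookup(af_catalog, population, match_mode)
    kept = []
    for v in variants:
        k = v.key if match_mode == "allele" else v.position_key
        af = lookup.get(k)
        if af is None or af <= threshold:
            kept.append(v)
    return kept


def run_cascade(
    cohort: Sequence[AnnotatedVariant],
    controls: Sequence[AnnotatedVariant],
    af_catalog: pd.DataFrame,
    config: Optional[FilterConfig] = None,
) -> Tuple[List[AnnotatedVariant], FilterTrace]:
    """Apply coding restriction, control subtraction and population-AF
    filtering in order, returning survivors plus the audit trace."""
    config = config or FilterConfig()
    trace = FilterTrace()

    coding = restrict_coding(cohort, config.coding_consequences)
    trace.record("restrict_coding", len(cohort), len(coding))

    private = subtract_controls(coding, controls, config.match_mode)
    trace.record("subtract_controls", len(coding), len(private))

    rare = filter_population_af(
        private, af_catalog, config.af_population, config.af_threshold, config.match_mode
    )
    trace.record("filter_population_af", len(private), len(rare))
    return rare, trace
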