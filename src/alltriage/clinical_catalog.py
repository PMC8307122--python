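"""Clinical-evidence levels, mutational-significance tiers, and pathways.

The tier engine ranks an amino-acid change by three boolean evidence
factors from a Cancer Mutation Census style snapshot:

  factor 1 — recurrent mutation in a Cancer Gene Census driver gene,
  factor 2 — pathogenic assertion in ClinVar,
  factor 3 — positive selection by the dN/dS ratio.

Tier 1 requires factors 1 and 2 together; Tier 2 any other pair of
factors; Tier 3 exactly one factor; "Other" none. On top of the census
tiers sits Tier X: a change at a residue position that carries Tier 1-3
census entries, but whose specific substitution is either uncatalogued
or catalogued with the label "other". Tier X flags positions of known
significance where the observed change itself is of unknown effect.

Clinical-evidence levels are an OncoKB-style 1-4 scale (1 =
FDA-recognized biomarker, 2 = standard-care, 3 = compelling clinical
evidence, 4 = compelling biological evidence) collapsed across the
diagnostic / prognostic / therapeutic categories; a gene's level is the
strongest (minimum) across categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .model import AnnotatedVariant, ProteinVariant

logger = logging.getLogger(__name__)

TIER1, TIER2, TIER3, OTHER, TIERX, UNRANKED = (
    "Tier1", "Tier2", "Tier3", "Other", "TierX", "Unranked",
)

#: severity order, strongest first (used by monotonicity checks)
TIER_SEVERITY = {TIER1: 0, TIER2: 1, TIER3: 2, OTHER: 3}


@dataclass(frozen=True)
class EvidenceFactors:
    """The three census evidence factors for one amino-acid change."""

    f_recurrent_driver: bool
    f_clinvar_pathogenic: bool
    f_dnds_selection: bool

    def count(self) -> int:
        return sum((self.f_recurrent_driver, self.f_clinvar_pathogenic, self.f_dnds_selection))


def tier_from_factors(factors: EvidenceFactors) -> str:
    """Rank a catalogued change from its evidence factors.

    Total over all 8 combinations; the Tier 1 rule (factors 1 and 2)
    takes precedence over the any-two Tier 2 rule, so a change meeting
    factors 1 and 2 is never Tier 2 regardless of factor 3.
    """
    if factors.f_recurrent_driver and factors.f_clinvar_pathogenic:
        return TIER1
    n = factors.count()
    if n >= 2:
        return TIER2
    if n == 1:
        return TIER3
    return OTHER


@dataclass
class TierCall:
    """Classification attached to one variant."""

    tier: str
    level: Optional[int] = None
    level_categories: List[str] = field(default_factory=list)
    pathways: List[str] = field(default_factory=list)
    basis: str = "none"  # match type: exact | position | none


class MutationCensus:
    """Indexed view of a mutation_census catalogue table."""

    def __init__(self, census: pd.DataFrame):
        self._exact: Dict[Tuple[str, int, str], dict] = {}
        self._position: Dict[Tuple[str, int], List[dict]] = {}
        for r in census.itertuples(index=False):
            rec = {
                "gene": r.gene, "aa_ref": r.aa_ref, "aa_pos": r.aa_pos, "aa_alt": r.aa_alt,
                "cmc_label": r.cmc_label,
                "tier": tier_from_factors(
                    EvidenceFactors(r.f_recurrent_driver, r.f_clinvar_pathogenic, r.f_dnds_selection)
                ),
            }
            self._exact[(r.gene, r.aa_pos, r.aa_alt)] = rec
            self._position.setdefault((r.gene, r.aa_pos), []).append(rec)

    def exact(self, gene: str, aa_pos: int, aa_alt: str) -> Optional[dict]:
        return self._exact.get((gene, aa_pos, aa_alt))

    def at_position(self, gene: str, aa_pos: int) -> List[dict]:
        return self._position.get((gene, aa_pos), [])

    def position_has_tiered(self, gene: str, aa_pos: int) -> bool:
        return any(rec["tier"] in (TIER1, TIER2, TIER3) for rec in self.at_position(gene, aa_pos))


def classify_variant_tier(pv: Optional[ProteinVariant], census: MutationCensus | pd.DataFrame) -> TierCall:
    """Assign the mutational-significance tier for one protein change.

    An exact (gene, position, ref, alt) census match takes that record's
    factor-derived tier — unless the record is labeled "other" while the
    position carries Tier 1-3 entries, in which case the call is Tier X.
    Without an exact match, a position holding any Tier 1-3 record
    yields Tier X; otherwise the change is Unranked. Frameshift tokens
    never match exactly (the census catalogues substitutions) but still
    qualify for position-level Tier X.
    """
    if isinstance(census, pd.DataFrame):
        census = MutationCensus(census)
    if pv is None:
        return TierCall(tier=UNRANKED, basis="none")

    rec = None if pv.is_frameshift else census.exact(pv.gene, pv.aa_pos, pv.aa_alt)
    if rec is not None and rec["aa_ref"] != pv.aa_ref:
        logger.warning(
            "%s %s: catalogue lists reference residue %s at position %d; "
            "treating as a position match",
            pv.gene, pv, rec["aa_ref"], pv.aa_pos,
        )
        rec = None
    if rec is not None:
        if rec["cmc_label"] == "other" and census.position_has_tiered(pv.gene, pv.aa_pos):
            return TierCall(tier=TIERX, basis="exact")
        return TierCall(tier=rec["tier"], basis="exact")
    if census.position_has_tiered(pv.gene, pv.aa_pos):
        return TierCall(tier=TIERX, basis="position")
    return TierCall(tier=UNRANKED, basis="none")


def assign_clinical_level(
    gene: str, clinical_levels: pd.DataFrame
) -> Tuple[Optional[int], List[str]]:
    """Strongest (minimum) evidence level for a gene across categories,
    with the categories attaining it; (None, []) for absent genes."""
    sub = clinical_levels[clinical_levels["gene"] == gene]
    if sub.empty:
        return None, []
    best = int(sub["level"].min())
    cats = sorted(sub.loc[sub["level"] == best, "category"].tolist())
    return best, cats


def map_pathway(gene: str, pathways: pd.DataFrame) -> List[str]:
    """All targetable-pathway memberships for a gene; empty when absent."""
    return sorted(pathways.loc[pathways["gene"] == gene, "pathway"].tolist())


def classify_variants(
    variants: Sequence[AnnotatedVariant],
    census: pd.DataFrame,
    clinical_levels: pd.DataFrame,
    pathways: pd.DataFrame,
) -> List[TierCall]:
    """Tier + level + pathway calls for a variant collection (order preserved)."""
    idx = MutationCensus(census)
    calls = []
    for v in variants:
        call = classify_variant_tier(v.protein_change, idx)
        call.level, call.level_categories = assign_clinical_level(v.gene, clinical_levels)
        call.pathways = map_pathway(v.gene, pathways)
        calls.append(call)
    return calls
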