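import numpy as np
import pytest
from hypothesis import settings

from alltriage.model import AnnotatedVariant
from alltriage.pipeline import RunConfig, run_pipeline
from alltriage.synthetic_data import borderland_fixture

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


def make_variant(
    chrom="chr1",
    pos=100,
    ref="A",
    alt="T",
    gene="GENE",
    consequence="missense_variant",
    protein_change=None,
    genotypes=None,
):
    """Terse constructor for in-memory variants in tests."""
    return AnnotatedVariant(
        chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
        consequence=consequence, protein_change=protein_change,
        protein_change_raw=str(protein_change) if protein_change else "",
        sample_genotypes=dict(genotypes or {"S1": 1}),
    )


def random_cohort(rng, n_variants=20, p_noncoding=0.3, p_in_controls=0.3, p_common=0.3):
    """Random in-memory (cohort, controls, af_table) triple with the truth
    of each stage's predicate, for cascade property tests."""
    import pandas as pd

    cohort, controls, af_rows = [], [], []
    truth = []
    for i in range(n_variants):
        coding = rng.random() >= p_noncoding
        v = make_variant(
            chrom="chrR", pos=10 + i, ref="A", alt="G", gene=f"G{i}",
            consequence="missense_variant" if coding else "intron_variant",
            genotypes={"P1": 1},
        )
        cohort.append(v)
        in_controls = rng.random() < p_in_controls
        if in_controls:
            controls.append(
                make_variant(chrom="chrR", pos=10 + i, ref="A", alt="G",
                             gene=f"G{i}", genotypes={"C1": 1})
            )
        common = rng.random() < p_common
        af = float(rng.uniform(0.06, 0.5)) if common else float(rng.uniform(1e-4, 0.05))
        if common or rng.random() < 0.5:
            af_rows.append(dict(gene=f"G{i}", chrom="chrR", pos=10 + i, ref="A",
                                alt="G", population="LAT", af=af))
        else:
            common = False  # uncatalogued rare allele
        truth.append(coding and not in_controls and not common)
    af_table = pd.DataFrame(
        af_rows, columns=["gene", "chrom", "pos", "ref", "alt", "population", "af"]
    )
    return cohort, controls, af_table, truth


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """The packaged borderland cohort bundle, materialized once."""
    return borderland_fixture(tmp_path_factory.mktemp("borderland"))


@pytest.fixture(scope="session")
def fixture_result(fixture_bundle, tmp_path_factory):
    """Full pipeline result on the borderland bundle."""
    out = tmp_path_factory.mktemp("borderland_out")
    config = RunConfig(
        cohort_vcfs=fixture_bundle.patient_vcfs,
        control_vcfs=fixture_bundle.control_vcfs,
        population_af=fixture_bundle.population_af,
        mutation_census=fixture_bundle.mutation_census,
        clinical_levels=fixture_bundle.clinical_levels,
        pathways=fixture_bundle.pathways,
        metadata=fixture_bundle.metadata,
        out_dir=out,
        groups=[("KRAS", 12)],
        stratify_by="status",
    )
    return run_pipeline(config)
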