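"""VCF/catalogue I/O and protein-change notation."""

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from alltriage.model import AA_CODES, ProteinChangeError, ProteinVariant
from alltriage.variant_io import (
    CatalogError,
    format_protein_change,
    merge_variants,
    parse_protein_change,
    read_catalog,
    read_variant_table,
    read_vcf,
    write_variant_table,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=ANN,Number=.,Type=String,Description="gene|consequence|protein_change">\n'
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=chr1>\n"
)


def _write_vcf(path, body, samples=("s1", "s2")):
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    path.write_text(VCF_HEADER + cols + "\n" + body)
    return path


class TestParseProteinChange:
    @pytest.mark.parametrize(
        "token, expected",
        [
            ("G12A", ("G", 12, "A")),
            ("C303*", ("C", 303, "*")),
            ("C303 *", ("C", 303, "*")),  # tables sometimes print a space
            ("N642H", ("N", 642, "H")),
            ("E2366*", ("E", 2366, "*")),
            ("K100fs", ("K", 100, "fs")),
        ],
    )
    def test_components_extracted(self, token, expected):
        pv = parse_protein_change(token, gene="X")
        assert (pv.aa_ref, pv.aa_pos, pv.aa_alt) == expected

    @pytest.mark.parametrize("token", ["", "12A", "G12", "GxA", "G0A", "G12G", "B12A", "p.G12A"])
    def test_rejects_invalid_tokens(self, token):
        with pytest.raises(ProteinChangeError):
            parse_protein_change(token)

    @given(
        aa_ref=st.sampled_from(sorted(AA_CODES)),
        aa_pos=st.integers(min_value=1, max_value=99999),
        aa_alt=st.sampled_from(sorted(AA_CODES) + ["*", "fs"]),
    )
    def test_roundtrip_identity(self, aa_ref, aa_pos, aa_alt):
        """parse(format(pv)) is the identity over all valid tokens."""
        if aa_ref == aa_alt:
            return
        pv = ProteinVariant(gene="G", aa_ref=aa_ref, aa_pos=aa_pos, aa_alt=aa_alt)
        back = parse_protein_change(format_protein_change(pv), gene="G")
        assert (back.aa_ref, back.aa_pos, back.aa_alt) == (aa_ref, aa_pos, aa_alt)


class TestReadVcf:
    def test_biallelic_site_dosages(self, tmp_path):
        p = _write_vcf(
            tmp_path / "a.vcf",
            "chr1\t100\t.\tA\tT\t.\tPASS\tANN=KRAS|missense_variant|G12A\tGT\t0/1\t0/0\n",
        )
        (v,) = read_vcf(p)
        assert v.sample_genotypes == {"s1": 1, "s2": 0}
        assert (v.gene, v.consequence, str(v.protein_change)) == (
            "KRAS", "missense_variant", "G12A",
        )

    def test_triallelic_site_split_into_two_records(self, tmp_path):
        p = _write_vcf(
            tmp_path / "a.vcf",
            "chr1\t100\t.\tA\tT,G\t.\tPASS\t"
            "ANN=KRAS|missense_variant|G12A,KRAS|missense_variant|G12D\tGT\t1/2\t0/1\n",
        )
        v1, v2 = read_vcf(p)
        assert (v1.chrom, v1.pos, v1.ref) == (v2.chrom, v2.pos, v2.ref)
        assert {v1.alt, v2.alt} == {"T", "G"}
        # per-alt dosages: s1 is het for both alts, s2 only for the first
        assert v1.sample_genotypes == {"s1": 1, "s2": 1}
        assert v2.sample_genotypes == {"s1": 1, "s2": 0}

    def test_split_conserves_total_alt_allele_count(self, tmp_path):
        p = _write_vcf(
            tmp_path / "a.vcf",
            "chr1\t100\t.\tA\tT,G\t.\tPASS\t"
            "ANN=K|missense_variant|G12A,K|missense_variant|G12D\tGT\t1/2\t2/2\n",
        )
        variants = read_vcf(p)
        total = sum(d for v in variants for d in v.sample_genotypes.values())
        assert total == 4  # 1+1 from s1, 0+2 from s2

    def test_missing_and_malformed_annotation_kept_unannotated(self, tmp_path):
        p = _write_vcf(
            tmp_path / "a.vcf",
            "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t./.\n"
            "chr1\t200\t.\tC\tG\t.\tPASS\tANN=onlytwo|fields\tGT\t0/1\t0/0\n",
        )
        v1, v2 = read_vcf(p)
        assert v1.consequence == "unannotated"
        assert v1.sample_genotypes["s2"] is None
        assert v2.consequence == "unannotated"

    def test_unparseable_protein_change_keeps_raw_string(self, tmp_path):
        p = _write_vcf(
            tmp_path / "a.vcf",
            "chr1\t100\t.\tA\tT\t.\tPASS\tANN=KRAS|missense_variant|c.35G>C\tGT\t0/1\t0/0\n",
        )
        (v,) = read_vcf(p)
        assert v.protein_change is None
        assert v.protein_change_raw == "c.35G>C"

    def test_malformed_vcf_raises_parse_error(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("not a vcf at all\n")
        with pytest.raises(Exception):
            read_vcf(p)

    def test_roundtrip_preserves_key_multiset(self, tmp_path):
        """read -> write (generator) -> read preserves (chrom,pos,ref,alt,gene,dosage)."""
        from alltriage.synthetic_data import write_sample_vcf

        p = _write_vcf(
            tmp_path / "a.vcf",
            "chr1\t100\t.\tA\tT\t.\tPASS\tANN=K|missense_variant|G12A\tGT\t0/1\t1/1\n"
            "chr1\t200\t.\tC\tG\t.\tPASS\tANN=W|stop_gained|C303*\tGT\t0/0\t0/1\n",
        )
        variants = read_vcf(p)
        for sample in ("s1", "s2"):
            q = tmp_path / f"{sample}.vcf"
            write_sample_vcf(
                q, sample,
                [
                    dict(chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt, gene=v.gene,
                         consequence=v.consequence, protein_change=v.change_label,
                         dosage=v.sample_genotypes[sample])
                    for v in variants
                ],
            )
        back = merge_variants(
            v for sample in ("s1", "s2") for v in read_vcf(tmp_path / f"{sample}.vcf")
        )
        orig = sorted((v.key, v.gene, s, d) for v in variants
                      for s, d in v.sample_genotypes.items())
        got = sorted((v.key, v.gene, s, d) for v in back
                     for s, d in v.sample_genotypes.items())
        assert got == orig


class TestReadCatalog:
    def test_population_af_row_accepted(self, tmp_path):
        p = tmp_path / "af.tsv"
        p.write_text(
            "gene\tchrom\tpos\tref\talt\tpopulation\taf\n"
            "KRAS\tchr12\t25245350\tC\tG\tLAT\t0.001\n"
        )
        df = read_catalog(p, "population_af")
        assert df.loc[0, "af"] == 0.001

    def test_factor_flags_outside_01_rejected(self, tmp_path):
        p = tmp_path / "cmc.tsv"
        p.write_text(
            "gene\taa_ref\taa_pos\taa_alt\tf_recurrent_driver\t"
            "f_clinvar_pathogenic\tf_dnds_selection\tcmc_label\n"
            "KRAS\tG\t12\tA\t2\t0\t0\ttier1\n"
        )
        with pytest.raises(CatalogError, match="f_recurrent_driver"):
            read_catalog(p, "mutation_census")

    def test_clinical_level_row_accepted(self, tmp_path):
        p = tmp_path / "lvl.tsv"
        p.write_text("gene\tcategory\tlevel\nROS1\ttherapeutic\t1\n")
        df = read_catalog(p, "clinical_levels")
        assert df.loc[0, "level"] == 1

    def test_duplicate_key_rejected(self, tmp_path):
        p = tmp_path / "lvl.tsv"
        p.write_text("gene\tcategory\tlevel\nROS1\ttherapeutic\t1\nROS1\ttherapeutic\t2\n")
        with pytest.raises(CatalogError, match="duplicate"):
            read_catalog(p, "clinical_levels")

    def test_missing_column_and_unknown_kind_rejected(self, tmp_path):
        p = tmp_path / "lvl.tsv"
        p.write_text("gene\tlevel\nROS1\t1\n")
        with pytest.raises(CatalogError, match="missing required column"):
            read_catalog(p, "clinical_levels")
        with pytest.raises(CatalogError, match="unknown catalogue kind"):
            read_catalog(p, "nope")


class TestVariantTable:
    def _rows(self):
        return [
            {
                "sample": "P8", "gene": "KRAS", "chrom": "chr12", "pos": 25245350,
                "ref": "C", "alt": "G", "protein_change": "G12A",
                "consequence": "missense_variant", "tier": "Tier1", "level": 1,
                "pathway": "MAPK", "status": "new-onset",
            },
            {
                "sample": "P1", "gene": "ATM", "chrom": "chr11", "pos": 108365000,
                "ref": "G", "alt": "T", "protein_change": "E2366*",
                "consequence": "stop_gained", "tier": "TierX", "level": 1,
                "pathway": "DNA damage response", "status": "relapse",
            },
        ]

    def test_empty_input_header_only(self, tmp_path):
        out = tmp_path / "t.tsv"
        write_variant_table([], out)
        assert out.read_text().strip() == "\t".join(
            ["sample", "gene", "chrom", "pos", "ref", "alt", "protein_change",
             "consequence", "tier", "level", "pathway", "status"]
        )

    def test_rows_ordered_and_roundtrip(self, tmp_path):
        out = tmp_path / "t.tsv"
        df = write_variant_table(self._rows(), out)
        assert df["gene"].tolist() == ["ATM", "KRAS"]  # gene-major order
        back = read_variant_table(out)
        assert set(zip(back["sample"], back["gene"], back["protein_change"], back["tier"])) == {
            ("P8", "KRAS", "G12A", "Tier1"),
            ("P1", "ATM", "E2366*", "TierX"),
        }
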