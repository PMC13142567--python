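"""Allele matching: truth table vs exhaustive enumeration, and invariances."""

import itertools

import numpy as np
import pytest

from grexstream.engine import EngineConfig, stream_impute
from grexstream.errors import DataError, FormatError
from grexstream.fixtures import FixtureSpec, generate_cohort
from grexstream.genotype_io import TextDosageSource, parse_psam, parse_pvar
from grexstream.harmonize import (
    MATCHED_STATUSES,
    MatchStatus,
    VariantKey,
    build_matched_index,
    complement_allele,
    is_strand_ambiguous,
    match_variant,
    orient_alleles,
)
from grexstream.weights_io import WeightRecord, build_weight_index, load_weight_table

from conftest import CollectingSink

BASES = "ACGT"
COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def oracle_status(effect, other, ref, alt):
    """Independent exhaustive case analysis of one ordered orientation.

    Enumerates which of the four interpretations (exact, swapped, complement,
    complement-swapped) are consistent with the site, then applies the rules:
    exact wins outright; any other interpretation at a complementary-pair
    site is undecidable (ambiguous strand); otherwise the unique surviving
    interpretation is the answer.
    """
    consistent = set()
    if (other, effect) == (ref, alt):
        consistent.add("exact")
    if (effect, other) == (ref, alt):
        consistent.add("swapped")
    if (COMP[other], COMP[effect]) == (ref, alt):
        consistent.add("complement")
    if (COMP[effect], COMP[other]) == (ref, alt):
        consistent.add("complement_swapped")
    if "exact" in consistent:
        return "exact"
    if not consistent:
        return "unmatched"
    if is_strand_ambiguous(effect, other):
        return "ambiguous_strand"
    assert len(consistent) == 1  # exclusive for non-ambiguous pairs
    return consistent.pop()


ORDERED_PAIRS = [(a, b) for a, b in itertools.product(BASES, BASES) if a != b]


class TestComplementAllele:
    @pytest.mark.parametrize("allele,expected", [
        ("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("AG", "CT"), ("ACGT", "ACGT"),
    ])
    def test_complement(self, allele, expected):
        assert complement_allele(allele) == expected

    def test_involution(self):
        for a, b in ORDERED_PAIRS:
            assert complement_allele(complement_allele(a + b)) == a + b

    def test_non_acgt_rejected(self):
        with pytest.raises(FormatError):
            complement_allele("N")


class TestMatchVariantTruthTable:
    def make_manifest(self, tmp_path, ref, alt, name="one"):
        path = tmp_path / f"{name}_{ref}_{alt}.pvar"
        path.write_text(
            "#CHROM\tPOS\tID\tREF\tALT\n" f"chr1\t100\trs1\t{ref}\t{alt}\n"
        )
        return parse_pvar(path)

    def test_all_orientation_cases(self, tmp_path):
        """match_variant agrees with exhaustive enumeration on every ordered
        (effect, other) x (REF, ALT) combination of distinct bases."""
        for ref, alt in ORDERED_PAIRS:
            manifest = self.make_manifest(tmp_path, ref, alt)
            for effect, other in ORDERED_PAIRS:
                result = match_variant(
                    VariantKey("chr1", 100, effect, other), manifest
                )
                expected = oracle_status(effect, other, ref, alt)
                assert result.status.value == expected, (effect, other, ref, alt)
                assert (result.genotype_ordinal is not None) == (
                    result.status in MATCHED_STATUSES
                )
                if result.status in MATCHED_STATUSES:
                    expect_flip = expected in ("swapped", "complement_swapped")
                    assert (result.dosage_transform == "flip") == expect_flip

    def test_matching_is_a_function(self, tmp_path):
        manifest = self.make_manifest(tmp_path, "A", "G")
        key = VariantKey("chr1", 100, "C", "T")
        results = {match_variant(key, manifest) for _ in range(5)}
        assert len(results) == 1
        assert results.pop().status == MatchStatus.COMPLEMENT

    def test_spec_orientation_examples(self, tmp_path):
        manifest = self.make_manifest(tmp_path, "A", "G")
        exact = match_variant(VariantKey("chr1", 100, "G", "A"), manifest)
        assert (exact.status, exact.dosage_transform) == (MatchStatus.EXACT, "identity")
        swapped = match_variant(VariantKey("chr1", 100, "A", "G"), manifest)
        assert (swapped.status, swapped.dosage_transform) == (MatchStatus.SWAPPED, "flip")
        comp = match_variant(VariantKey("chr1", 100, "C", "T"), manifest)
        assert (comp.status, comp.dosage_transform) == (MatchStatus.COMPLEMENT, "identity")

    def test_ambiguous_pair_only_exact(self, tmp_path):
        manifest = self.make_manifest(tmp_path, "A", "T")
        exact = match_variant(VariantKey("chr1", 100, "T", "A"), manifest)
        assert exact.status == MatchStatus.EXACT
        needs_comp = match_variant(VariantKey("chr1", 100, "A", "T"), manifest)
        assert needs_comp.status == MatchStatus.AMBIGUOUS_STRAND
        assert needs_comp.genotype_ordinal is None

    def test_indels_match_without_complement(self, tmp_path):
        manifest = self.make_manifest(tmp_path, "A", "AG")
        assert match_variant(VariantKey("chr1", 100, "AG", "A"), manifest).status == MatchStatus.EXACT
        assert match_variant(VariantKey("chr1", 100, "A", "AG"), manifest).status == MatchStatus.SWAPPED
        # complement of the pair would hit (T, CT); no complementation for indels
        manifest2 = self.make_manifest(tmp_path, "T", "CT", name="b")
        assert match_variant(VariantKey("chr1", 100, "AG", "A"), manifest2).status == MatchStatus.UNMATCHED


class TestEffectOnlyOrientation:
    """Plain-table predictors carry only the effect allele."""

    def test_all_single_allele_cases(self):
        for ref, alt in ORDERED_PAIRS:
            amb = is_strand_ambiguous(ref, alt)
            for effect in BASES:
                status, transform = orient_alleles(effect, None, ref, alt)
                if effect == alt:
                    expected = "exact"
                elif effect == ref:
                    expected = "ambiguous_strand" if amb else "swapped"
                elif COMP[effect] == alt:
                    expected = "complement"
                elif COMP[effect] == ref:
                    expected = "complement_swapped"
                else:
                    expected = "unmatched"
                assert status.value == expected, (effect, ref, alt)
                if status in MATCHED_STATUSES:
                    assert (transform == "flip") == (expected.endswith("swapped") and
                                                    not expected.startswith("ambiguous"))


class TestBuildMatchedIndex:
    def make_inputs(self, tmp_path):
        pvar = tmp_path / "c.pvar"
        pvar.write_text(
            "#CHROM\tPOS\tID\tREF\tALT\n"
            "chr1\t100\trs1\tA\tG\n"
            "chr1\t200\trs2\tC\tT\n"
            "chr1\t300\trs3\tA\tT\n"  # strand-ambiguous site
        )
        manifest = parse_pvar(pvar)
        records = [
            WeightRecord("chr1", "EUR", "m1", "G1", "rs1", "G", None, 0.5),   # exact
            WeightRecord("chr1", "EUR", "m1", "G1", "rs2", "C", None, -0.2),  # swapped
            WeightRecord("chr1", "EUR", "m1", "G1", "rs9", "A", None, 0.3),   # absent
            WeightRecord("chr1", "EUR", "m1", "G2", "rs3", "A", None, 0.4),   # ambiguous
        ]
        catalog, index = build_weight_index(records)
        return records, catalog, manifest, index

    def test_exclusion_accounting(self, tmp_path):
        records, catalog, manifest, index = self.make_inputs(tmp_path)
        matched, report = build_matched_index(records, catalog, manifest, index)
        assert matched.total_entries == 2
        assert (report.n_matched, report.n_unmatched, report.n_ambiguous) == (2, 1, 1)
        assert report.n_total == len(records)
        frame = report.to_frame()
        assert set(frame["status"]) == {"exact", "swapped", "unmatched", "ambiguous_strand"}

    def test_column_losing_all_variants_still_owned(self, tmp_path):
        records, catalog, manifest, index = self.make_inputs(tmp_path)
        matched, report = build_matched_index(records, catalog, manifest, index)
        g2 = catalog.index[("EUR", "m1", "G2")]
        assert g2 in matched.owned_columns
        assert matched.matched_count.get(g2, 0) == 0
        coverage = report.coverage_frame(catalog)
        assert coverage.loc[coverage["gene"] == "G2", "coverage"].item() == 0.0

    def test_flip_arithmetic_zeroes_homozygous_effect(self, tmp_path):
        """Effect allele = REF with dosage 2 contributes w*(2-2) = 0."""
        pvar = tmp_path / "one.pvar"
        pvar.write_text("#CHROM\tPOS\tID\tREF\tALT\nchr1\t100\trs1\tA\tG\n")
        manifest = parse_pvar(pvar)
        records = [WeightRecord("chr1", "EUR", "m1", "G1", "rs1", "A", None, 0.7)]
        catalog, index = build_weight_index(records)
        matched, _ = build_matched_index(records, catalog, manifest, index)
        ((col, w, flip),) = matched.entries_by_ordinal[0]
        assert flip
        dosage = 2.0
        assert w * (2.0 - dosage) == 0.0


class TestReencodingInvariance:
    """Swapping REF/ALT in both the manifest and the dosages must not move
    predictions (flip arithmetic: w*(2-(2-d)) == w*d)."""

    def run_engine(self, root, spec_dirname):
        weights = load_weight_table(root / "weights.tsv")
        catalog, index = build_weight_index(weights)
        prefix = root / "geno" / "cohort_chr1"
        manifest = parse_pvar(f"{prefix}.pvar")
        samples = parse_psam(f"{prefix}.psam")
        matched, _ = build_matched_index(
            [r for r in weights if r.chromosome == "chr1"], catalog, manifest, index
        )
        source = TextDosageSource(f"{prefix}.dosage.tsv", samples)
        sink = CollectingSink()
        stream_impute(source, matched, catalog, samples, EngineConfig(snp_chunk_size=17), sink)
        return sink.as_matrix(samples.n_analyzed, catalog.k)

    def test_swapped_encoding_same_predictions(self, tmp_path):
        spec = FixtureSpec(
            n_samples=40, n_variants_per_chrom=60, chromosomes=("chr1",),
            n_models=2, genes_per_model=4, variants_per_gene=5,
            missing_rate=0.0, frac_swapped=0.3, frac_complemented=0.3,
            frac_ambiguous_sites=0.0, seed=23,
        )
        generate_cohort(spec, tmp_path / "orig")
        y_orig = self.run_engine(tmp_path / "orig", "orig")

        # Re-encode: swap REF/ALT in the .pvar and complement every dosage.
        import shutil
        shutil.copytree(tmp_path / "orig", tmp_path / "swapped")
        prefix = tmp_path / "swapped" / "geno" / "cohort_chr1"
        lines = (prefix.with_suffix(".pvar")).read_text().splitlines()
        out = []
        for line in lines:
            if line.startswith("#"):
                out.append(line)
            else:
                chrom, pos, vid, ref, alt = line.split("\t")
                out.append("\t".join([chrom, pos, vid, alt, ref]))
        prefix.with_suffix(".pvar").write_text("\n".join(out) + "\n")
        dos = np.loadtxt(f"{prefix}.dosage.tsv")
        np.savetxt(f"{prefix}.dosage.tsv", 2.0 - dos, delimiter="\t", fmt="%g")
        y_swapped = self.run_engine(tmp_path / "swapped", "swapped")

        scale = np.abs(y_orig).max()
        assert np.abs(y_orig - y_swapped).max() <= 1e-12 * max(scale, 1.0)
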