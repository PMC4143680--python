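import numpy as np
import pandas as pd
import pytest

from pathkin.regions import (
    GeneModelTable,
    GenotypeMatrix,
    PathwayRegionSet,
    RegionError,
    build_regions,
    extract_genotypes,
    maf_filter,
    parse_gmt,
    read_regions_bed,
    read_transcript_table,
    read_vcf,
    subset_by_regions,
    write_regions_bed,
)
from pathkin.simulate import SimConfig, simulate_study, write_vcf
from tests.conftest import make_genotypes


@pytest.fixture
def models():
    return GeneModelTable(
        pd.DataFrame(
            {
                "gene": ["G1", "G1", "G2", "G3", "G3", "G4"],
                "transcript": ["t1a", "t1b", "t2", "t3b", "t3a", "t4"],
                "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2", "chr2"],
                "strand": ["+", "+", "-", "+", "+", "-"],
                "txStart": [10_001, 10_001, 3_000, 50_000, 52_000, 90_000],
                "txEnd": [12_000, 15_000, 4_000, 60_000, 62_000, 91_000],
            }
        )
    )


class TestParseGmt:
    def test_shared_gene_in_two_pathways(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("PW1\tdesc\tG1\tG2\nPW2\tdesc\tG2\tG3\n")
        sets = parse_gmt(p)
        assert [name for name, _ in sets] == ["PW1", "PW2"]
        assert "G2" in dict(sets)["PW1"] and "G2" in dict(sets)["PW2"]

    def test_too_few_fields_errors_with_line_number(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("PW1\tdesc\tG1\nPW2\tdesc\n")
        with pytest.raises(RegionError, match=":2"):
            parse_gmt(p)

    def test_empty_gene_list_errors(self, tmp_path):
        p = tmp_path / "bad.gmt"
        p.write_text("PW1\tdesc\t\t\n")
        with pytest.raises(RegionError):
            parse_gmt(p)

    def test_five_pathways_map_to_five_region_sets(self, tmp_path, models):
        p = tmp_path / "five.gmt"
        p.write_text(
            "".join(f"PW{i}\td\tG{1 + i % 4}\n" for i in range(5))
        )
        sets = parse_gmt(p)
        region_sets = [
            build_regions(genes, models, name=name) for name, genes in sets
        ]
        assert len(region_sets) == 5


class TestBuildRegions:
    def test_longest_isoform_and_window_arithmetic(self, models):
        rs = build_regions(["G1"], models, flank=5000)
        gene, chrom, start, end = rs.regions[0]
        assert (gene, chrom) == ("G1", "chr1")
        assert (start, end) == (5_001, 20_000)  # longest isoform 10001-15000

    def test_window_clipped_at_one(self, models):
        rs = build_regions(["G2"], models, flank=5000)
        _, _, start, end = rs.regions[0]
        assert start == 1
        assert end == 9_000

    def test_span_tie_takes_lexicographically_smallest_transcript(self, models):
        # G3 isoforms t3a (52000-62000) and t3b (50000-60000): equal spans
        rs = build_regions(["G3"], models, flank=0)
        _, _, start, end = rs.regions[0]
        assert (start, end) == (52_000, 62_000)  # t3a < t3b

    def test_missing_symbols_skipped_and_recorded(self, models):
        rs = build_regions(["G1", "NOPE"], models)
        assert rs.missing_genes == ["NOPE"]
        assert rs.n_genes == 1

    def test_zero_resolvable_genes_errors(self, models):
        with pytest.raises(RegionError, match="no requested gene"):
            build_regions(["NOPE1", "NOPE2"], models)

    def test_case_insensitive_and_version_suffix(self, models):
        rs = build_regions(["g1.3"], models)
        assert rs.n_genes == 1

    def test_strand_aware_flanks(self, models):
        rs = build_regions(
            ["G4"], models, flank=0, strand_aware=True, upstream=1000, downstream=100
        )
        _, _, start, end = rs.regions[0]
        # G4 on minus strand: upstream flank applies on the right
        assert (start, end) == (90_000 - 100, 91_000 + 1000)

    def test_flank_monotonicity(self, models):
        small = build_regions(["G1", "G2"], models, flank=100)
        big = build_regions(["G1", "G2"], models, flank=5000)
        for (_, _, s1, e1), (_, _, s2, e2) in zip(small.regions, big.regions):
            assert s2 <= s1 and e1 <= e2


class TestTranscriptTableIO:
    def test_roundtrip(self, models, tmp_path):
        path = tmp_path / "tx.tsv"
        models.write(path)
        again = read_transcript_table(path)
        assert len(again.df) == len(models.df)

    def test_bed_input_converts_coordinates(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t100\t200\ttx1|GENE1\t0\t+\n")
        models = read_transcript_table(p)
        row = models.lookup("GENE1").iloc[0]
        assert (row["txStart"], row["txEnd"]) == (101, 200)

    def test_start_after_end_rejected(self):
        with pytest.raises(RegionError, match="start > end"):
            GeneModelTable(
                pd.DataFrame(
                    {
                        "gene": ["G"], "transcript": ["t"], "chrom": ["chr1"],
                        "strand": ["+"], "txStart": [10], "txEnd": [5],
                    }
                )
            )


@pytest.fixture
def toy_vcf(tmp_path):
    """Three SNVs (one inside the window 1000-2000), one multi-allelic, one
    indel, plus a missing genotype."""
    path = tmp_path / "toy.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
        "chr1\t500\tv0\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t0/0\n"
        "chr1\t1000\tv1\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t./.\n"
        "chr1\t1500\tv2\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/2\t0/0\n"
        "chr1\t1600\tv3\tAT\tA\t.\tPASS\t.\tGT\t0/1\t0/0\t0/0\n"
        "chr1\t2000\tv4\tC\tT\t.\tPASS\t.\tGT\t1/1\t0/1\t0/0\n"
        "chr1\t2500\tv5\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
    )
    return path


def _window(name="PW", gene="G", chrom="chr1", start=1000, end=2000):
    return PathwayRegionSet(name=name, regions=[(gene, chrom, start, end)])


class TestExtractGenotypes:
    def test_window_and_inclusive_boundaries(self, toy_vcf):
        g = extract_genotypes(toy_vcf, _window(), max_missing=1.0)
        # v1 (pos 1000) and v4 (pos 2000) inclusive; v2 multi-allelic and v3
        # indel skipped; v0/v5 outside
        assert list(g.variants["id"]) == ["v1", "v4"]

    def test_missing_genotype_preserved(self, toy_vcf):
        g = extract_genotypes(toy_vcf, _window(), max_missing=1.0)
        col = g.dosages[:, list(g.variants["id"]).index("v1")]
        assert np.isnan(col[2])

    def test_high_missingness_dropped_by_default(self, toy_vcf):
        g = extract_genotypes(toy_vcf, _window())  # v1 is 1/3 missing > 20%
        assert list(g.variants["id"]) == ["v4"]

    def test_minor_allele_flip(self, toy_vcf):
        g = extract_genotypes(toy_vcf, _window(), max_missing=1.0)
        j = list(g.variants["id"]).index("v4")
        # alt frequency of v4 = 3/6 > minor? equal; no flip at exactly 0.5
        assert g.maf[j] == pytest.approx(0.5)
        assert g.dosages[:, j].tolist() == [2.0, 1.0, 0.0]

    def test_overlapping_windows_deduplicate(self, toy_vcf):
        rs = PathwayRegionSet(
            name="PW",
            regions=[("G1", "chr1", 900, 2100), ("G2", "chr1", 1500, 2500)],
        )
        g = extract_genotypes(toy_vcf, rs, max_missing=1.0)
        assert list(g.variants["id"]) == ["v1", "v4", "v5"]
        assert g.variants["id"].is_unique

    def test_extraction_idempotent_and_region_order_independent(self, toy_vcf):
        regions = [("G1", "chr1", 900, 2100), ("G2", "chr1", 1500, 2500)]
        a = extract_genotypes(
            toy_vcf, PathwayRegionSet(name="PW", regions=regions),
            max_missing=1.0,
        )
        b = extract_genotypes(
            toy_vcf, PathwayRegionSet(name="PW", regions=regions[::-1]),
            max_missing=1.0,
        )
        assert set(a.variants["id"]) == set(b.variants["id"])
        again = extract_genotypes(
            toy_vcf, PathwayRegionSet(name="PW", regions=regions),
            max_missing=1.0,
        )
        np.testing.assert_allclose(a.dosages, again.dosages, equal_nan=True)

    def test_no_variants_gives_empty_sentinel(self, toy_vcf):
        g = extract_genotypes(toy_vcf, _window(start=10_000, end=20_000))
        assert g.is_empty
        assert g.samples == ["S1", "S2", "S3"]

    def test_sample_mismatch_lists_offenders(self, toy_vcf):
        with pytest.raises(KeyError, match="S9"):
            extract_genotypes(toy_vcf, _window(), samples=["S1", "S9"])

    def test_extraction_matches_in_memory_subset(self, tmp_path):
        study = simulate_study(
            SimConfig(n_families=2, generations=2, genes_per_pathway=3,
                      variants_per_gene=5, seed=3)
        )
        vcf = tmp_path / "sim.vcf"
        write_vcf(vcf, study.genotypes, study.haplotypes)
        rs = build_regions(
            study.gene_sets[0][1], study.gene_models, flank=5000, name="P1"
        )
        from_vcf = extract_genotypes(vcf, rs)
        in_mem = subset_by_regions(study.genotypes, rs)
        np.testing.assert_allclose(from_vcf.dosages, in_mem.dosages,
                                   equal_nan=True)


class TestMafFilter:
    def test_strict_inequality_at_threshold(self):
        # one variant with MAF exactly 0.05 (1 of 20 alleles), one below
        d = np.zeros((10, 2))
        d[0, 0] = 1.0  # MAF 0.05
        g = make_genotypes(d)
        out = maf_filter(g, 0.05)
        # MAF 0.05 is not < 0.05 and is removed; the monomorphic variant stays
        assert list(out.variants["id"]) == ["v2"]
        out2 = maf_filter(g, 0.06)
        assert out2.n_variants == 2

    def test_half_threshold_keeps_all_but_maf_half(self):
        d = np.array([[0, 1], [1, 1], [0, 1], [1, 1]], dtype=float)
        g = make_genotypes(d)  # second variant MAF 0.5
        out = maf_filter(g, 0.5)
        assert out.n_variants == 1

    def test_counted_fixture(self, rng):
        mafs = np.array([0.001, 0.004, 0.02, 0.009, 0.3, 0.15, 0.0005, 0.4,
                         0.05, 0.2])
        n = 2000
        d = rng.binomial(2, mafs, size=(n, 10)).astype(float)
        g = make_genotypes(d)
        out = maf_filter(g, 0.01)
        # by construction only the 4 rare variants can pass; realized MAFs at
        # n=2000 stay near truth
        assert out.n_variants == 4

    def test_composition_property(self, rng):
        d = rng.binomial(2, rng.uniform(0.0, 0.5, 30), size=(200, 30)).astype(float)
        g = make_genotypes(d)
        a, b = 0.3, 0.1
        lhs = maf_filter(maf_filter(g, a), b)
        rhs = maf_filter(g, min(a, b))
        np.testing.assert_allclose(lhs.dosages, rhs.dosages, equal_nan=True)

    def test_bad_threshold(self):
        g = make_genotypes(np.zeros((4, 2)))
        with pytest.raises(ValueError):
            maf_filter(g, 0.0)
        with pytest.raises(ValueError):
            maf_filter(g, 0.7)

    def test_all_removed_gives_empty_sentinel(self, rng):
        d = rng.binomial(2, 0.4, size=(50, 5)).astype(float)
        g = make_genotypes(d)
        out = maf_filter(g, 0.001)
        assert out.is_empty


class TestGenotypeMatrix:
    def test_rejects_bad_dosage(self):
        with pytest.raises(ValueError, match="dosages"):
            make_genotypes(np.array([[0.0, 3.0]]))

    def test_take_samples_unknown(self):
        g = make_genotypes(np.zeros((2, 2)))
        with pytest.raises(KeyError):
            g.take_samples(["S1", "NOPE"])

    def test_flip_normalization(self):
        d = np.array([[2, 0], [2, 0], [1, 0], [2, 1]], dtype=float)
        g = make_genotypes(d)  # variant 1 alt freq 7/8 -> flipped
        assert bool(g.variants["flipped"][0])
        assert (g.maf <= 0.5).all()
        assert g.dosages[0, 0] == 0.0


class TestRegionsBedIO:
    def test_roundtrip(self, models, tmp_path):
        rs1 = build_regions(["G1", "G2"], models, name="PW1")
        rs2 = build_regions(["G3"], models, name="PW2")
        path = tmp_path / "regions.bed"
        write_regions_bed(path, [rs1, rs2])
        back = {rs.name: rs for rs in read_regions_bed(path)}
        assert back["PW1"].regions == rs1.regions
        assert back["PW2"].regions == rs2.regions

    def test_bad_bed_errors(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\n")
        with pytest.raises(RegionError, match="7 columns"):
            read_regions_bed(p)


def test_read_vcf_loads_all_snvs(toy_vcf):
    g = read_vcf(toy_vcf, max_missing=1.0)
    assert g.n_variants == 4  # v0, v1, v4, v5 (multi-allelic + indel skipped)
    assert g.samples == ["S1", "S2", "S3"]
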