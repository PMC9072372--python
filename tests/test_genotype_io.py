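"""PLINK I/O, panel merging and missingness QC."""

import numpy as np
import pytest

from breedtrace import (
    GenotypeMatrix,
    Sample,
    SnpRecord,
    mean_impute,
    merge_panels,
    qc_filter,
    read_plink,
    write_plink,
)
from breedtrace.genotype_io import (
    MISSING,
    EmptyAfterQcError,
    PlinkFormatError,
)
from .conftest import random_genotype_matrix


# ---------------------------------------------------------------------------
# reading / writing


class TestReadPlink:
    def test_hand_written_text_fixture(self, tmp_path):
        """Allele-B dosages counted by eye from a 2-sample, 3-SNP .ped."""
        (tmp_path / "toy.map").write_text(
            "1 rs1 0 100\n2 rs2 0 200\n3 rs3 0 300\n"
        )
        # ind1: A A | C T | G G   ind2: A G | T T | 0 0
        (tmp_path / "toy.ped").write_text(
            "breedX ind1 0 0 0 -9 A A C T G G\n"
            "breedY ind2 0 0 0 -9 A G T T 0 0\n"
        )
        g = read_plink(tmp_path / "toy", dialect="text")
        assert g.sample_ids == ["ind1", "ind2"]
        assert [s.breed for s in g.samples] == ["breedX", "breedY"]
        # rs1: alleles A/G -> dosages of G are 0 and 1
        # rs2: alleles C/T -> dosages of T are 1 and 2
        # rs3: only G seen; ind2 is missing
        assert g.calls[0].tolist() == [0, 1, 0]
        assert g.calls[1].tolist() == [1, 2, MISSING]

    def test_missing_code_maps_to_missing(self, tmp_path):
        (tmp_path / "t.map").write_text("1 rs1 0 1\n")
        (tmp_path / "t.ped").write_text(
            "b i1 0 0 0 -9 0 0\nb i2 0 0 0 -9 A A\n"
        )
        g = read_plink(tmp_path / "t", dialect="text")
        assert g.calls[0, 0] == MISSING

    def test_field_count_mismatch_raises(self, tmp_path):
        (tmp_path / "t.map").write_text("1 rs1 0 1\n1 rs2 0 2\n")
        (tmp_path / "t.ped").write_text("b i1 0 0 0 -9 A A\n")
        with pytest.raises(PlinkFormatError):
            read_plink(tmp_path / "t", dialect="text")

    def test_unknown_allele_raises(self, tmp_path):
        (tmp_path / "t.map").write_text("1 rs1 0 1\n")
        (tmp_path / "t.ped").write_text("b i1 0 0 0 -9 A N\n")
        with pytest.raises(PlinkFormatError):
            read_plink(tmp_path / "t", dialect="text")

    def test_bad_bed_magic_raises(self, tmp_path):
        g = random_genotype_matrix(4, 6, seed=0)
        write_plink(g, tmp_path / "x", dialect="binary")
        raw = (tmp_path / "x.bed").read_bytes()
        (tmp_path / "x.bed").write_bytes(b"\x00\x00\x00" + raw[3:])
        with pytest.raises(PlinkFormatError, match="magic"):
            read_plink(tmp_path / "x", dialect="binary")


class TestWritePlink:
    @pytest.mark.parametrize("dialect", ["text", "binary"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_identity(self, tmp_path, dialect, seed):
        g = random_genotype_matrix(20, 50, seed=seed)
        write_plink(g, tmp_path / "rt", dialect=dialect)
        assert read_plink(tmp_path / "rt", dialect=dialect) == g

    def test_round_trip_across_dialects(self, tmp_path):
        """Binary and text encodings of the same panel agree cell by cell."""
        g = random_genotype_matrix(11, 17, seed=5)  # n % 4 != 0: pad bytes
        write_plink(g, tmp_path / "a", dialect="binary")
        write_plink(g, tmp_path / "b", dialect="text")
        ga = read_plink(tmp_path / "a", dialect="binary")
        gb = read_plink(tmp_path / "b", dialect="text")
        assert np.array_equal(ga.calls, gb.calls)

    def test_empty_matrix_rejected(self, tmp_path):
        g = random_genotype_matrix(2, 2, seed=0)
        empty = GenotypeMatrix(samples=[], snps=g.snps, calls=np.empty((0, 2)))
        with pytest.raises(ValueError):
            write_plink(empty, tmp_path / "e")

    def test_homozygote_written_as_allele_b_twice(self, tmp_path):
        g = GenotypeMatrix(
            samples=[Sample("i1", "b1")],
            snps=[SnpRecord("rs1", 1, 100, "A", "G")],
            calls=np.array([[2]], dtype=np.int8),
        )
        write_plink(g, tmp_path / "h", dialect="text")
        line = (tmp_path / "h.ped").read_text().strip()
        assert line.split()[-2:] == ["G", "G"]


# ---------------------------------------------------------------------------
# merging


def _panel(snp_defs, calls, breed="p"):
    snps = [SnpRecord(*d) for d in snp_defs]
    calls = np.asarray(calls, dtype=np.int8)
    samples = [Sample(f"{breed}{i}", breed) for i in range(calls.shape[0])]
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


class TestMergePanels:
    def test_identical_panels_keep_all_autosomal_snps(self, random_panel):
        with pytest.warns(UserWarning, match="duplicate sample_ids"):
            merged = merge_panels(random_panel, random_panel)
        assert merged.snp_ids == random_panel.snp_ids
        assert merged.n == 2 * random_panel.n

    def test_allele_swap_recodes_two_minus_g(self):
        a = _panel([("rs1", 1, 10, "A", "C")], [[0], [1]], breed="a")
        b = _panel([("rs1", 1, 10, "C", "A")], [[0], [2]], breed="b")
        merged = merge_panels(a, b)
        assert merged.calls[:, 0].tolist() == [0, 1, 2, 0]

    def test_complementary_strand_harmonized(self):
        # A/C in one panel, T/G (other strand) in the other: same SNP
        a = _panel([("rs1", 1, 10, "A", "C")], [[1]], breed="a")
        b = _panel([("rs1", 1, 10, "T", "G")], [[2]], breed="b")
        merged = merge_panels(a, b)
        assert merged.m == 1
        assert merged.calls[:, 0].tolist() == [1, 2]

    def test_complementary_swapped_strand_recoded(self):
        # G/T read on the other strand is C/A, i.e. A/C swapped
        a = _panel([("rs1", 1, 10, "A", "C")], [[1]], breed="a")
        b = _panel([("rs1", 1, 10, "G", "T")], [[0]], breed="b")
        merged = merge_panels(a, b)
        assert merged.calls[:, 0].tolist() == [1, 2]

    def test_symmetric_snp_sets(self, random_panel):
        other = random_genotype_matrix(5, 30, seed=9)
        with pytest.warns(UserWarning):
            ab = merge_panels(random_panel, other)
            ba = merge_panels(other, random_panel)
        assert set(ab.snp_ids) == set(ba.snp_ids)

    def test_ambiguous_snp_with_discordant_labels_dropped(self):
        a = _panel([("rs1", 1, 10, "A", "T")], [[0]], breed="a")
        b = _panel([("rs1", 1, 10, "T", "A")], [[0]], breed="b")
        with pytest.warns(UserWarning, match="ambiguous"):
            merged, report = merge_panels(a, b, return_report=True)
        assert merged.m == 0
        assert report.n_dropped_ambiguous == 1

    def test_irreconcilable_alleles_dropped_with_warning(self):
        a = _panel([("rs1", 1, 10, "A", "C")], [[0]], breed="a")
        b = _panel([("rs1", 1, 10, "A", "G")], [[0]], breed="b")
        with pytest.warns(UserWarning):
            merged, report = merge_panels(a, b, return_report=True)
        assert merged.m == 0
        assert report.n_dropped_irreconcilable == 1

    def test_non_autosomal_snps_excluded(self):
        a = _panel([("rs1", 19, 10, "A", "C"), ("rs2", 3, 20, "A", "C")],
                   [[0, 1]], breed="a")
        b = _panel([("rs1", 19, 10, "A", "C"), ("rs2", 3, 20, "A", "C")],
                   [[0, 1]], breed="b")
        merged = merge_panels(a, b)
        assert merged.snp_ids == ["rs2"]
        assert all(1 <= s.chromosome <= 18 for s in merged.snps)


# ---------------------------------------------------------------------------
# QC and imputation


class TestQcFilter:
    def test_strict_threshold_semantics(self):
        """12% missing removed; exactly 10% retained ('more than' is strict)."""
        g = random_genotype_matrix(4, 50, seed=1, missing_rate=0.0)
        calls = g.calls.copy()
        calls[0, :6] = MISSING   # 12%
        calls[1, :5] = MISSING   # exactly 10%
        g = GenotypeMatrix(samples=g.samples, snps=g.snps, calls=calls)
        filtered, report = qc_filter(g, max_snp_missing=1.0)
        assert [s for s, _ in report.samples_removed] == ["ind0"]
        assert "ind1" in filtered.sample_ids

    def test_fully_observed_matrix_untouched(self):
        g = random_genotype_matrix(6, 10, seed=2, missing_rate=0.0)
        filtered, report = qc_filter(g)
        assert filtered == g
        assert not report.samples_removed and not report.snps_removed

    def test_hand_counted_fixture(self, qc_fixture):
        filtered, report = qc_filter(qc_fixture)
        assert (filtered.n, filtered.m) == (4, 19)
        assert [s for s, _ in report.samples_removed] == ["ind0"]
        assert [s for s, _ in report.snps_removed] == ["rs5"]
        assert report.samples_removed[0][1] == pytest.approx(0.15)
        assert report.snps_removed[0][1] == pytest.approx(0.25)

    def test_idempotent(self, qc_fixture):
        once, _ = qc_filter(qc_fixture)
        twice, report2 = qc_filter(once)
        assert twice == once
        assert not report2.samples_removed and not report2.snps_removed

    def test_post_qc_missingness_bounded(self):
        g = random_genotype_matrix(30, 40, seed=3, missing_rate=0.08)
        filtered, _ = qc_filter(g)
        miss = filtered.missing_mask()
        assert (miss.mean(axis=1) <= 0.10).all()
        assert (miss.mean(axis=0) <= 0.05).all()

    def test_all_samples_removed_raises(self):
        g = random_genotype_matrix(3, 10, seed=4, missing_rate=0.0)
        calls = np.full_like(g.calls, MISSING)
        g = GenotypeMatrix(samples=g.samples, snps=g.snps, calls=calls)
        with pytest.raises(EmptyAfterQcError):
            qc_filter(g)

    def test_report_csv_round_trip(self, qc_fixture, tmp_path):
        import pandas as pd

        _, report = qc_filter(qc_fixture)
        report.to_csv(tmp_path / "qc.csv")
        df = pd.read_csv(tmp_path / "qc.csv")
        assert set(df["entity"]) == {"sample", "snp"}
        assert (df["action"] == "removed").all()


class TestMeanImpute:
    def test_column_mean_fills_missing(self):
        g = _panel([("rs1", 1, 10, "A", "C")], [[0], [2], [MISSING]])
        x = mean_impute(g)
        assert x[:, 0].tolist() == [0.0, 2.0, 1.0]

    def test_identity_without_missing(self):
        g = random_genotype_matrix(8, 12, seed=5, missing_rate=0.0)
        assert np.array_equal(mean_impute(g), g.calls.astype(float))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_imputed_column_means_equal_observed_means(self, seed):
        g = random_genotype_matrix(25, 30, seed=seed, missing_rate=0.2)
        x = mean_impute(g)
        obs = np.ma.masked_array(g.calls, mask=g.missing_mask())
        np.testing.assert_allclose(x.mean(axis=0), obs.mean(axis=0))

    def test_all_missing_snp_raises(self):
        g = _panel([("rs1", 1, 10, "A", "C")], [[MISSING], [MISSING]])
        with pytest.raises(ValueError, match="zero observed"):
            mean_impute(g)
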