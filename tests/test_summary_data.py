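import numpy as np
import pytest

from cismr.summary_data import (LDReference, SummaryStats, VariantRecord,
                                harmonize, ld_from_genotypes, read_ld_matrix,
                                read_summary_stats, write_summary_stats)

from conftest import make_variants


def _write_tsv(path, rows, header="snp\tchr\tpos\tea\tnea\teaf\tbeta\tse\tpval\tn"):
    path.write_text(header + "\n" + "\n".join(rows) + "\n")


class TestReadSummaryStats:
    def test_round_trip_preserves_numeric_fields(self, tmp_path):
        f = tmp_path / "exp.tsv"
        _write_tsv(f, [
            "rs1\t1\t100\tA\tG\t0.25\t0.123456789012345\t0.01\t1e-10\t5000",
            "rs2\t1\t200\tC\tT\t0.5\t-0.2\t0.02\t0.5\t5000",
            "rs3\t1\t300\tG\tA\t0.75\t0.0\t0.03\t1.0\t5000",
        ])
        stats = read_summary_stats(f, role="exposure")
        assert stats.n_variants == 3
        assert stats.n_x == 5000
        g = tmp_path / "back.tsv"
        write_summary_stats(stats, g, role="exposure")
        again = read_summary_stats(g, role="exposure")
        np.testing.assert_array_equal(stats.beta_x, again.beta_x)
        np.testing.assert_array_equal(stats.se_x, again.se_x)
        np.testing.assert_array_equal(stats.p_x, again.p_x)
        np.testing.assert_array_equal(stats.eaf, again.eaf)

    def test_missing_se_column_is_named(self, tmp_path):
        f = tmp_path / "bad.tsv"
        f.write_text("snp\tea\tnea\teaf\tbeta\tpval\nrs1\tA\tG\t0.3\t0.1\t0.5\n")
        with pytest.raises(ValueError, match="'se'"):
            read_summary_stats(f)

    def test_out_of_range_eaf_row_goes_to_parse_report(self, tmp_path):
        f = tmp_path / "eaf.tsv"
        _write_tsv(f, [
            "rs1\t1\t100\tA\tG\t1.2\t0.1\t0.01\t0.5\t100",
            "rs2\t1\t200\tA\tG\t0.3\t0.1\t0.01\t0.5\t100",
        ])
        stats = read_summary_stats(f)
        assert stats.snp_ids == ["rs2"]
        (line, snp, reason), = stats.parse_report.rejected
        assert (line, snp) == (2, "rs1") and "eaf" in reason

    def test_non_numeric_beta_is_hard_error_with_line(self, tmp_path):
        f = tmp_path / "num.tsv"
        _write_tsv(f, ["rs1\t1\t100\tA\tG\t0.3\tnotanumber\t0.01\t0.5\t100"])
        with pytest.raises(ValueError, match="line 2"):
            read_summary_stats(f)


class TestLDMatrixIO:
    def test_square_dialect_identity(self, tmp_path):
        f = tmp_path / "ld.txt"
        f.write_text("rs1\trs2\n1.0\t0.0\n0.0\t1.0\n")
        ld = read_ld_matrix(f)
        assert ld.snp_ids == ["rs1", "rs2"]
        np.testing.assert_array_equal(ld.corr, np.eye(2))

    def test_long_dialect_fills_both_triangles(self, tmp_path):
        f = tmp_path / "ld.txt"
        f.write_text("rsA rsB 0.3\n")
        ld = read_ld_matrix(f)
        assert ld.corr[0, 1] == ld.corr[1, 0] == 0.3

    def test_asymmetry_beyond_tolerance_rejected(self, tmp_path):
        f = tmp_path / "ld.txt"
        f.write_text("a\tb\n1.0\t0.5\n0.4\t1.0\n")
        with pytest.raises(ValueError, match="asymmetric"):
            read_ld_matrix(f)

    def test_non_square_rejected(self, tmp_path):
        f = tmp_path / "ld.txt"
        f.write_text("a\tb\n1.0\t0.2\n")
        with pytest.raises(ValueError, match="square"):
            read_ld_matrix(f)

    def test_off_unit_diagonal_rejected(self, tmp_path):
        f = tmp_path / "ld.txt"
        f.write_text("a\tb\n0.9\t0.2\n0.2\t1.0\n")
        with pytest.raises(ValueError, match="diagonal"):
            read_ld_matrix(f)


class TestLDFromGenotypes:
    def test_identical_columns_give_unit_correlation(self):
        g = np.array([[0, 0], [1, 1], [2, 2], [1, 1]])
        ld = ld_from_genotypes(g, make_variants(2))
        assert ld.corr[0, 1] == pytest.approx(1.0)
        assert ld.n_ref == 4

    def test_independent_columns_have_small_sample_correlation(self):
        rng = np.random.default_rng(11)
        g = rng.binomial(2, 0.3, size=(10_000, 2))
        ld = ld_from_genotypes(g, make_variants(2))
        assert abs(ld.corr[0, 1]) < 0.05

    def test_constant_column_error_names_variant(self):
        g = np.array([[0, 1], [0, 2], [0, 0]])
        with pytest.raises(ValueError, match="snp0"):
            ld_from_genotypes(g, make_variants(2))


def _one_sided(variants, beta, se, role, n=1000, p=None):
    if role == "exposure":
        if p is None:
            p = np.full(len(variants), 0.01)
        return SummaryStats(variants, beta_x=np.asarray(beta, float),
                            se_x=np.asarray(se, float), p_x=p, n_x=n)
    return SummaryStats(variants, beta_y=np.asarray(beta, float),
                        se_y=np.asarray(se, float), n_y=n)


class TestHarmonize:
    def setup_method(self):
        self.variants = make_variants(2, eaf=[0.3, 0.4])
        self.corr = np.array([[1.0, 0.5], [0.5, 1.0]])
        self.ld = LDReference(self.variants, self.corr)
        self.exp = _one_sided(self.variants, [0.2, 0.1], [0.01, 0.01], "exposure")

    def test_identical_coding_is_untouched(self):
        out = _one_sided(self.variants, [0.1, 0.05], [1.0, 2.0], "outcome")
        data = harmonize(self.exp, out, self.ld)
        assert data.dropped == []
        np.testing.assert_array_equal(data.stats.beta_y, [0.1, 0.05])

    def test_omega_is_se_scaled_correlation(self):
        # se_y = (1, 2), rho = 0.5 -> omega = [[1, 1], [1, 4]]
        out = _one_sided(self.variants, [0.1, 0.05], [1.0, 2.0], "outcome")
        data = harmonize(self.exp, out, self.ld)
        np.testing.assert_allclose(data.omega, [[1.0, 1.0], [1.0, 4.0]])

    def test_swapped_outcome_allele_flips_beta_sign(self):
        flipped = [self.variants[0].flipped(), self.variants[1]]
        out = SummaryStats(flipped, beta_y=np.array([0.1, 0.05]),
                           se_y=np.array([1.0, 2.0]), n_y=1000)
        data = harmonize(self.exp, out, self.ld)
        np.testing.assert_allclose(data.stats.beta_y, [-0.1, 0.05])

    def test_swapped_ld_allele_flips_row_and_column(self):
        ld_flipped = LDReference([self.variants[0].flipped(), self.variants[1]],
                                 self.corr)
        out = _one_sided(self.variants, [0.1, 0.05], [1.0, 2.0], "outcome")
        data = harmonize(self.exp, out, ld_flipped)
        assert data.ld.corr[0, 1] == pytest.approx(-0.5)
        assert data.omega[0, 1] == pytest.approx(-1.0)

    def test_allele_flip_is_involutive(self):
        # flipping outcome coding AND negating beta describes the same GWAS,
        # so harmonization must produce identical results
        out = _one_sided(self.variants, [0.1, 0.05], [1.0, 2.0], "outcome")
        refl = SummaryStats([v.flipped() for v in self.variants],
                            beta_y=np.array([-0.1, -0.05]),
                            se_y=np.array([1.0, 2.0]), n_y=1000)
        d1 = harmonize(self.exp, out, self.ld)
        d2 = harmonize(self.exp, refl, self.ld)
        np.testing.assert_allclose(d1.stats.beta_y, d2.stats.beta_y)
        np.testing.assert_allclose(d1.omega, d2.omega)

    def test_mismatched_alleles_dropped_with_reason(self):
        other = [VariantRecord("snp0", "1", 1, "C", "T", 0.3), self.variants[1]]
        out = _one_sided(other, [0.1, 0.05], [1.0, 2.0], "outcome")
        data = harmonize(self.exp, out, self.ld)
        assert data.dropped == [("snp0", "allele_mismatch")]
        assert data.stats.snp_ids == ["snp1"]

    def test_palindromic_dropped_only_when_requested(self):
        pal = [VariantRecord("snp0", "1", 1, "A", "T", 0.3), self.variants[1]]
        exp = _one_sided(pal, [0.2, 0.1], [0.01, 0.01], "exposure")
        out = _one_sided(pal, [0.1, 0.05], [1.0, 2.0], "outcome")
        ld = LDReference(pal, self.corr)
        assert harmonize(exp, out, ld).n_variants == 2
        data = harmonize(exp, out, ld, drop_palindromic=True)
        assert data.dropped == [("snp0", "palindromic")]

    def test_empty_intersection_is_hard_error(self):
        other = make_variants(2, prefix="other")
        out = _one_sided(other, [0.1, 0.05], [1.0, 2.0], "outcome")
        with pytest.raises(ValueError, match="no variants shared"):
            harmonize(self.exp, out, self.ld)


def test_omega_psd_under_congruence():
    """diag(se) R diag(se) stays PSD for any PSD correlation matrix."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        p = rng.integers(2, 6)
        f = rng.normal(size=(p, p + 2))
        cov = f @ f.T
        d = np.sqrt(np.diag(cov))
        corr = cov / np.outer(d, d)
        se = rng.uniform(0.1, 3.0, p)
        omega = corr * np.outer(se, se)
        assert np.linalg.eigvalsh(omega).min() > -1e-10


def test_variant_record_validation():
    with pytest.raises(ValueError, match="identical"):
        VariantRecord("x", "1", 1, "A", "A", 0.5)
    with pytest.raises(ValueError, match="eaf"):
        VariantRecord("x", "1", 1, "A", "G", 1.5)
    with pytest.raises(ValueError, match="duplicate"):
        SummaryStats(make_variants(2) + [make_variants(1)[0]],
                     beta_x=np.zeros(3), se_x=np.ones(3),
                     p_x=np.full(3, 0.5))
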