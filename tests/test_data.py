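import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pmsblup.data import (
    MISSING,
    ParseError,
    compute_call_rate,
    compute_maf,
    correct_phenotypes,
    maf_distribution,
    qc_filter,
    read_dosage_tsv,
    read_vcf,
    write_dosage_tsv,
    write_vcf,
)

from conftest import make_genotypes, random_genotypes


class TestCallRateAndMaf:
    def test_call_rate_examples(self):
        g = make_genotypes(np.array([[0], [MISSING], [2], [1]]))
        assert compute_call_rate(g)[0] == 0.75
        assert compute_call_rate(make_genotypes([[MISSING], [MISSING]]))[0] == 0.0
        assert compute_call_rate(make_genotypes([[1], [2]]))[0] == 1.0

    @pytest.mark.parametrize(
        "column, expected",
        [
            ([0, 0, 1, 2], 0.375),
            ([0, 2, MISSING], 0.5),
            ([0, 0, 0, 0], 0.0),
        ],
    )
    def test_maf_examples(self, column, expected):
        g = make_genotypes(np.array(column)[:, None])
        assert compute_maf(g)[0] == pytest.approx(expected)

    def test_maf_all_missing_is_flagged_nan(self):
        g = make_genotypes([[MISSING], [MISSING]])
        assert np.isnan(compute_maf(g)[0])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        arrays(
            np.int16,
            st.tuples(st.integers(2, 8), st.integers(1, 6)),
            elements=st.sampled_from([MISSING, 0, 1, 2]),
        )
    )
    def test_maf_relabeling_property(self, dosages):
        """MAF is a property of the genotype distribution, not the labels."""
        g = make_genotypes(dosages)
        flipped = make_genotypes(np.where(dosages == MISSING, MISSING, 2 - dosages))
        np.testing.assert_allclose(
            compute_maf(g), compute_maf(flipped), atol=1e-12, equal_nan=True
        )
        cr = compute_call_rate(g)
        assert ((cr >= 0) & (cr <= 1)).all()

    def test_maf_invariant_to_allele_relabeling(self, rng):
        g = random_genotypes(rng, 40, 25)
        flipped = make_genotypes(
            np.where(g.dosages == MISSING, MISSING, 2 - g.dosages)
        )
        np.testing.assert_allclose(compute_maf(g), compute_maf(flipped), atol=1e-12)


class TestQcFilter:
    def test_low_call_rate_marker_removed(self):
        d = np.array([[0, 0], [MISSING, 1], [2, 2], [MISSING, 1]])
        kept, report = qc_filter(make_genotypes(d))
        assert list(kept.marker_ids) == ["snp2"]
        assert report.loc[0, "reason"] == "call_rate"

    def test_rare_allele_removed(self):
        d = np.zeros((100, 1), dtype=int)
        d[0, 0] = 1  # one minor copy among 100 individuals: MAF 0.005
        kept, _ = qc_filter(make_genotypes(d))
        assert kept.n_markers == 0

    def test_toy_panel_single_survivor(self, toy_qc_panel):
        kept, report = qc_filter(toy_qc_panel)
        assert list(kept.marker_ids) == ["snp3"]
        # brute-force check of the report against direct recomputation
        for j in range(toy_qc_panel.n_markers):
            col = toy_qc_panel.dosages[:, j]
            cr = np.mean(col != MISSING)
            assert report.loc[j, "call_rate"] == pytest.approx(cr)
            assert report.loc[j, "kept"] == (
                cr > 0.70 and report.loc[j, "maf"] >= 0.01
            )

    def test_idempotent(self, rng):
        g = random_genotypes(rng, 30, 50, maf_low=0.0, maf_high=0.3)
        once, _ = qc_filter(g)
        twice, _ = qc_filter(once)
        assert list(twice.marker_ids) == list(once.marker_ids)
        np.testing.assert_array_equal(twice.dosages, once.dosages)


class TestCorrectPhenotypes:
    def test_sex_effect_removed(self):
        p = pd.DataFrame(
            {
                "id": list("abcd"),
                "trait": [10.0, 10.0, 6.0, 6.0],
                "sex": ["M", "M", "F", "F"],
                "batch": ["B1"] * 4,
            }
        )
        yc = correct_phenotypes(p)
        np.testing.assert_allclose(yc["yc"], [8.0, 8.0, 8.0, 8.0])

    def test_single_level_factors_leave_y_unchanged(self):
        p = pd.DataFrame(
            {"id": ["a", "b"], "trait": [1.0, 2.0], "sex": "M", "batch": "B1"}
        )
        np.testing.assert_allclose(correct_phenotypes(p)["yc"], [1.0, 2.0])

    def test_balanced_design_matches_normal_equations(self):
        # balanced 2 sex x 2 batch with additive effects (+2/-2) and (+1/-1)
        sex = np.array(["M", "M", "F", "F"] * 2)
        batch = np.array(["B1", "B2"] * 4)
        base = np.array([5.0, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0])
        y = base + np.where(sex == "M", 2.0, -2.0) + np.where(batch == "B1", 1.0, -1.0)
        p = pd.DataFrame(
            {"id": [f"i{k}" for k in range(8)], "trait": y, "sex": sex, "batch": batch}
        )
        # independent oracle: solve the sum-to-zero normal equations directly
        X = np.column_stack(
            [
                np.ones(8),
                np.where(sex == "M", 1.0, -1.0),
                np.where(batch == "B1", 1.0, -1.0),
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        expected = y - X[:, 1:] @ beta[1:]
        np.testing.assert_allclose(correct_phenotypes(p)["yc"], expected, atol=1e-10)

    def test_residual_orthogonal_to_design(self, rng):
        n = 60
        p = pd.DataFrame(
            {
                "id": [f"i{k}" for k in range(n)],
                "trait": rng.normal(size=n),
                "sex": rng.choice(["M", "F"], n),
                "batch": rng.choice([f"B{j}" for j in range(1, 7)], n),
            }
        )
        yc = correct_phenotypes(p)["yc"].to_numpy()
        vy = p["trait"].var()
        for col in ["sex", "batch"]:
            for level in p[col].unique()[:-1]:
                x = (p[col] == level).astype(float)
                assert abs(np.cov(yc, x, ddof=1)[0, 1]) < 1e-6 * max(vy, 1.0)

    def test_confounded_factors_raise(self):
        p = pd.DataFrame(
            {
                "id": list("abcd"),
                "trait": [1.0, 2.0, 3.0, 4.0],
                "sex": ["M", "M", "F", "F"],
                "batch": ["B1", "B1", "B2", "B2"],  # aliased with sex
            }
        )
        with pytest.raises(ValueError, match="confounded"):
            correct_phenotypes(p)


class TestRoundTrip:
    def test_dosage_tsv_round_trip(self, tmp_path):
        g = make_genotypes([[0, 1], [2, MISSING], [1, 0]])
        path = tmp_path / "geno.tsv"
        write_dosage_tsv(g, path)
        back = read_dosage_tsv(path)
        assert back.individual_ids == g.individual_ids
        np.testing.assert_array_equal(back.dosages, g.dosages)

    def test_vcf_round_trip(self, tmp_path, rng):
        g = random_genotypes(rng, 5, 8)
        d = g.dosages.copy()
        d[0, 0] = MISSING
        g = make_genotypes(d)
        path = tmp_path / "geno.vcf"
        write_vcf(g, path)
        back = read_vcf(path)
        assert back.individual_ids == g.individual_ids
        assert list(back.marker_ids) == list(g.marker_ids)
        np.testing.assert_array_equal(back.dosages, g.dosages)

    def test_bad_dosage_names_location(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tsnp1\nA\t0\nB\t7\n")
        with pytest.raises(ParseError, match="line 3"):
            read_dosage_tsv(path)


class TestMafDistribution:
    def test_equal_bins_give_zero_cv(self):
        # one marker per 0.05-wide bin: MAF 0.025, 0.075, ..., 0.475
        cols = []
        n = 40
        for maf in np.arange(0.025, 0.5, 0.05):
            k = int(round(2 * n * maf))
            col = np.zeros(n, dtype=int)
            col[: k // 2] = 2
            if k % 2:
                col[k // 2] = 1
            cols.append(col)
        g = make_genotypes(np.array(cols).T)
        s = maf_distribution(g)
        assert s.counts.sum() == len(cols)
        assert s.cv == pytest.approx(0.0)

    def test_two_bin_arithmetic(self):
        # width 0.25 gives exactly two bins; 10 markers in the first, 20 in
        # the second -> mean 15, sample SD 7.0711, cv 0.4714
        cols = []
        n = 100
        for maf, count in [(0.10, 10), (0.30, 20)]:
            k = int(round(2 * n * maf))
            col = np.zeros(n, dtype=int)
            col[:k] = 1
            cols += [col] * count
        g = make_genotypes(np.array(cols).T)
        s = maf_distribution(g, bin_width=0.25)
        assert list(s.counts) == [10, 20]
        assert s.cv == pytest.approx(0.4714, abs=1e-4)

    def test_single_loaded_bin_matches_arithmetic(self):
        n = 50
        col = np.zeros(n, dtype=int)
        col[:20] = 1  # MAF 0.2 for every marker
        g = make_genotypes(np.array([col] * 6).T)
        s = maf_distribution(g, bin_width=0.1)  # bins [0,.1),[.1,.2),[.2,.3),[.3,.4),[.4,.5]
        counts = np.array([0, 0, 6, 0, 0])
        np.testing.assert_array_equal(s.counts, counts)
        assert s.cv == pytest.approx(counts.std(ddof=1) / counts.mean())

    def test_bad_width_raises(self, toy_qc_panel):
        with pytest.raises(ValueError):
            maf_distribution(toy_qc_panel, bin_width=0.0)
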