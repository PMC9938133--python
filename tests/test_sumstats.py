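"""Summary-statistics IO, validation, region exclusion, clumping, harmonisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tissuemr import (
    GenomicRegion,
    HLA_REGION,
    clump,
    exclude_region,
    harmonise,
    read_proxy_table,
    read_sumstats,
)
from tissuemr.sumstats import SumstatsError, validate_records

from conftest import make_table

DIALECT = {
    "rsid": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}


def _write_tsv(path, rows):
    cols = ["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


class TestReadSumstats:
    def test_parses_valid_rows(self, tmp_path):
        f = tmp_path / "ss.tsv"
        _write_tsv(
            f,
            [
                ["rs1", 1, 100, "A", "G", 0.2, 0.05, 0.01, 1e-8, 1000],
                ["rs2", 2, 200, "C", "T", 0.4, -0.02, 0.02, 0.3, 1000],
                ["rs3", "X", 300, "G", "C", 0.1, 0.01, 0.01, 0.5, 1000],
            ],
        )
        t = read_sumstats(f, DIALECT)
        assert len(t) == 3
        assert list(t.df["rsid"]) == ["rs1", "rs2", "rs3"]

    def test_nonpositive_se_row_excluded(self, tmp_path):
        f = tmp_path / "ss.tsv"
        _write_tsv(
            f,
            [
                ["rs1", 1, 100, "A", "G", 0.2, 0.05, 0.0, 1e-8, 1000],
                ["rs2", 2, 200, "C", "T", 0.4, -0.02, 0.02, 0.3, 1000],
            ],
        )
        t = read_sumstats(f, DIALECT)
        assert list(t.df["rsid"]) == ["rs2"]

    def test_optional_eaf_column_may_be_absent(self, tmp_path):
        f = tmp_path / "ss.tsv"
        _write_tsv(f, [["rs1", 1, 100, "A", "G", 0.2, 0.05, 0.01, 1e-8, 1000]])
        dialect = {k: v for k, v in DIALECT.items() if k != "eaf"}
        t = read_sumstats(f, dialect)
        assert "eaf" not in t.df.columns

    def test_bad_mapping_and_empty_file_raise(self, tmp_path):
        f = tmp_path / "ss.tsv"
        _write_tsv(f, [["rs1", 1, 100, "A", "G", 0.2, 0.05, 0.01, 1e-8, 1000]])
        with pytest.raises(SumstatsError, match="absent columns"):
            read_sumstats(f, dict(DIALECT, beta="NOPE"))
        g = tmp_path / "bad.tsv"
        _write_tsv(g, [["rs1", 1, 100, "A", "A", 0.2, 0.05, 0.01, 1e-8, 1000]])
        with pytest.raises(SumstatsError, match="no valid rows"):
            read_sumstats(g, DIALECT)

    def test_validation_reasons(self):
        df = pd.DataFrame(
            {
                "rsid": ["rs1", "rs2", "rs3", "rs3"],
                "effect_allele": ["A", "A", "C", "C"],
                "other_allele": ["G", "G", "T", "T"],
                "beta": [0.1, 0.1, 0.1, 0.1],
                "se": [0.01, 0.01, 0.01, 0.01],
                "pvalue": [0.5, 1.5, 0.1, 0.2],
                "eaf": [1.2, 0.3, 0.3, 0.3],
            }
        )
        clean, excluded = validate_records(df)
        assert set(clean["rsid"]) == {"rs3"}
        reasons = set(excluded["reason"])
        assert {"allele frequency outside (0,1)", "p-value outside (0,1]", "duplicate record"} == reasons


class TestExcludeRegion:
    @pytest.mark.parametrize(
        "chrom,pos,removed",
        [("6", 30_000_000, True), ("6", 24_999_999, False), ("7", 30_000_000, False),
         ("6", 25_000_000, True), ("6", 35_000_000, True)],
    )
    def test_hla_boundaries(self, chrom, pos, removed):
        t = make_table([{"chrom": chrom, "pos": pos}])
        out = exclude_region(t, HLA_REGION)
        assert (len(out) == 0) == removed

    def test_idempotent(self, rng):
        t = make_table(
            [{"chrom": "6", "pos": int(p)} for p in rng.integers(1, 50_000_000, 40)]
        )
        once = exclude_region(t, HLA_REGION)
        twice = exclude_region(once, HLA_REGION)
        pd.testing.assert_frame_equal(once.df, twice.df)


class TestClump:
    def test_p_threshold_is_strict(self):
        t = make_table(
            [{"pvalue": 6e-8, "chrom": "1", "pos": 1}, {"pvalue": 4e-8, "chrom": "2", "pos": 1}]
        )
        out = clump(t, p_threshold=5e-8)
        assert list(out.df["rsid"]) == ["rs001"]

    def test_greedy_ld_rule(self):
        t = make_table(
            [{"pvalue": 1e-9}, {"pvalue": 1e-8}, {"pvalue": 1e-10, "chrom": "2"}]
        )
        rs = list(t.df["rsid"])
        ld = pd.DataFrame(np.eye(3), index=rs, columns=rs)
        ld.iloc[0, 1] = ld.iloc[1, 0] = np.sqrt(0.5)  # r^2 = 0.5 between rs000/rs001
        out = clump(t, r2_threshold=0.01, ld=ld)
        assert set(out.df["rsid"]) == {"rs000", "rs002"}

    def test_uncorrelated_all_kept(self):
        t = make_table([{"pvalue": 1e-9}, {"pvalue": 1e-8}, {"pvalue": 1e-10}])
        rs = list(t.df["rsid"])
        ld = pd.DataFrame(np.eye(3), index=rs, columns=rs)
        assert len(clump(t, ld=ld)) == 3

    def test_distance_mode(self):
        t = make_table(
            [
                {"pvalue": 1e-9, "chrom": "1", "pos": 1_000_000},
                {"pvalue": 1e-8, "chrom": "1", "pos": 2_000_000},
                {"pvalue": 1e-8, "chrom": "1", "pos": 50_000_000},
            ]
        )
        out = clump(t, window_bp=10_000_000)
        assert set(out.df["rsid"]) == {"rs000", "rs002"}

    @given(st.randoms(use_true_random=False))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_shuffle_invariance(self, pyrand):
        rng = np.random.default_rng(1)
        t = make_table(
            [
                {"pvalue": p, "chrom": str(c), "pos": int(pos)}
                for p, c, pos in zip(
                    rng.choice([1e-9, 1e-10, 1e-12], 12),  # deliberate p ties
                    rng.integers(1, 4, 12),
                    rng.integers(1, 100_000_000, 12),
                )
            ]
        )
        baseline = clump(t)
        idx = list(range(12))
        pyrand.shuffle(idx)
        shuffled = t.with_df(t.df.iloc[idx])
        assert sorted(clump(shuffled).df["rsid"]) == sorted(baseline.df["rsid"])


class TestHarmonise:
    def test_swapped_alleles_flip_beta(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "G", "beta": 0.10}])
        out = make_table([{"effect_allele": "G", "other_allele": "A", "beta": 0.05}])
        h = harmonise(exp, out).df
        assert h.loc[0, "orientation"] == "flipped"
        assert h.loc[0, "beta_out"] == pytest.approx(-0.05)

    def test_strand_flip_keeps_sign(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "G", "beta": 0.10}])
        out = make_table([{"effect_allele": "T", "other_allele": "C", "beta": 0.05}])
        h = harmonise(exp, out).df
        assert h.loc[0, "orientation"] == "kept"
        assert h.loc[0, "beta_out"] == pytest.approx(0.05)

    def test_palindromic_resolved_by_frequency(self):
        # four-orientation enumeration: exposure EAF 0.10 vs outcome EAF 0.88
        # can only agree if the outcome is read on the opposite strand, i.e.
        # the outcome's stated effect allele is the exposure's other allele
        exp = make_table(
            [{"effect_allele": "A", "other_allele": "T", "beta": 0.10, "eaf": 0.10}]
        )
        out = make_table(
            [{"effect_allele": "A", "other_allele": "T", "beta": 0.05, "eaf": 0.88}]
        )
        h = harmonise(exp, out, palindromic_maf_limit=0.42).df
        assert h.loc[0, "orientation"] == "flipped"
        assert h.loc[0, "beta_out"] == pytest.approx(-0.05)
        assert h.loc[0, "eaf_out"] == pytest.approx(0.12)

    def test_palindromic_ambiguous_dropped(self):
        exp = make_table([{"effect_allele": "A", "other_allele": "T", "eaf": 0.50}])
        out = make_table([{"effect_allele": "A", "other_allele": "T", "eaf": 0.50}])
        h = harmonise(exp, out).df
        assert h.loc[0, "orientation"] == "dropped"
        assert h.loc[0, "reason"] == "palindromic-ambiguous"

    def test_self_harmonisation_identity(self, rng):
        t = make_table(
            [
                {
                    "effect_allele": ea,
                    "other_allele": oa,
                    "beta": float(b),
                    "eaf": float(f),
                }
                for (ea, oa), b, f in zip(
                    [("A", "G"), ("C", "T"), ("A", "T"), ("C", "G"), ("G", "A")],
                    rng.normal(0, 0.1, 5),
                    rng.uniform(0.05, 0.4, 5),
                )
            ]
        )
        h = harmonise(t, t)
        assert (h.df["orientation"] == "kept").all()
        np.testing.assert_allclose(h.df["beta_out"], h.df["beta_exp"])

    def test_sign_consistency_on_allele_swap(self, rng):
        """Re-expressing both studies on the other allele negates both betas."""
        exp = make_table(
            [{"effect_allele": "A", "other_allele": "G", "beta": 0.1, "eaf": 0.2},
             {"effect_allele": "C", "other_allele": "T", "beta": -0.3, "eaf": 0.3}]
        )
        out = make_table(
            [{"effect_allele": "A", "other_allele": "G", "beta": 0.05, "eaf": 0.2},
             {"effect_allele": "T", "other_allele": "C", "beta": 0.07, "eaf": 0.7}]
        )
        h1 = harmonise(exp, out).kept
        flipped = exp.df.copy()
        flipped["effect_allele"], flipped["other_allele"] = (
            exp.df["other_allele"],
            exp.df["effect_allele"],
        )
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        h2 = harmonise(exp.with_df(flipped), out).kept
        np.testing.assert_allclose(h2["beta_exp"], -h1["beta_exp"])
        np.testing.assert_allclose(h2["beta_out"], -h1["beta_out"])

    def test_missing_in_outcome_uses_proxy_else_drops(self, tmp_path):
        exp = make_table([{"beta": 0.1}, {"beta": 0.2}])  # rs000, rs001
        out = make_table([{"beta": 0.05}])
        out_df = out.df.copy()
        out_df["rsid"] = ["rsPROXY"]
        out_df["effect_allele"], out_df["other_allele"] = "C", "T"
        out = out.with_df(out_df)
        proxy_file = tmp_path / "proxies.tsv"
        pd.DataFrame(
            {
                "requested_rsid": ["rs000"],
                "proxy_rsid": ["rsPROXY"],
                "r2": [0.9],
                "proxy_effect_allele": ["C"],
                "proxy_other_allele": ["T"],
            }
        ).to_csv(proxy_file, sep="\t", index=False)
        h = harmonise(exp, out, proxies=read_proxy_table(proxy_file)).df
        byrs = h.set_index("rsid")
        assert byrs.loc["rs000", "reason"] == "proxy-substituted"
        assert byrs.loc["rs000", "orientation"] == "kept"
        assert byrs.loc["rs000", "beta_out"] == pytest.approx(0.05)
        assert byrs.loc["rs001", "reason"] == "missing-in-outcome"

    def test_low_r2_proxy_not_used(self, tmp_path):
        exp = make_table([{"beta": 0.1}])
        out = make_table([{"beta": 0.05}])
        out_df = out.df.assign(rsid=["rsPROXY"])
        proxies = pd.DataFrame(
            {
                "requested_rsid": ["rs000"],
                "proxy_rsid": ["rsPROXY"],
                "r2": [0.5],
                "proxy_effect_allele": ["A"],
                "proxy_other_allele": ["G"],
            }
        )
        h = harmonise(exp, out.with_df(out_df), proxies=proxies).df
        assert h.loc[0, "reason"] == "missing-in-outcome"


def test_region_validation():
    with pytest.raises(SumstatsError):
        GenomicRegion("1", 100, 50)
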