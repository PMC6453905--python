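import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surfdbm.expression import (
    AbundanceFormatError,
    AbundanceRecord,
    SampleMeta,
    aggregate_to_genes,
    assemble_matrix,
    compute_fpkm,
    compute_tpm,
    group_mean,
    read_abundance,
    read_matrix,
    read_sample_sheet,
    read_t2g,
    write_abundance,
    write_matrix,
)

from conftest import make_matrix, make_metas

HEADER = "target_id\tlength\teff_length\test_counts\ttpm\n"


class TestReadAbundance:
    def test_two_line_valid(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(HEADER + "t1\t1000\t800.5\t10\t5.5\nt2\t500\t300\t0\t0\n")
        recs = read_abundance(p)
        assert len(recs) == 2
        assert recs[0] == AbundanceRecord("t1", 1000, 800.5, 10.0, 5.5)

    def test_missing_eff_length_column(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("target_id\tlength\test_counts\ttpm\nt1\t1000\t10\t5\n")
        with pytest.raises(AbundanceFormatError, match="header"):
            read_abundance(p)

    def test_non_numeric_field_cites_line(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(HEADER + "t1\t1000\t800\t10\t5\nt2\t500\t300\tNA\t0\n")
        with pytest.raises(AbundanceFormatError, match=":3"):
            read_abundance(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("")
        with pytest.raises(AbundanceFormatError, match="empty"):
            read_abundance(p)

    def test_header_only(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(HEADER)
        with pytest.raises(AbundanceFormatError, match="no data rows"):
            read_abundance(p)

    def test_negative_counts_rejected(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text(HEADER + "t1\t1000\t800\t-1\t5\n")
        with pytest.raises(AbundanceFormatError, match=":2"):
            read_abundance(p)

    @settings(max_examples=30, deadline=None)
    @given(
        values=st.lists(
            st.tuples(
                st.floats(1, 1e5), st.floats(0, 1e6), st.floats(0, 1e6)
            ),
            min_size=1,
            max_size=20,
        )
    )
    def test_roundtrip_six_significant_digits(self, tmp_path_factory, values):
        recs = [
            AbundanceRecord(f"t{i}", 100 + i, el, c, t)
            for i, (el, c, t) in enumerate(values)
        ]
        p = tmp_path_factory.mktemp("rt") / "a.tsv"
        write_abundance(p, recs)
        back = read_abundance(p)
        assert len(back) == len(recs)
        for a, b in zip(recs, back):
            assert a.transcript_id == b.transcript_id
            assert b.eff_length == pytest.approx(a.eff_length, rel=1e-5)
            assert b.est_counts == pytest.approx(a.est_counts, rel=1e-5, abs=1e-9)
            assert b.tpm == pytest.approx(a.tpm, rel=1e-5, abs=1e-9)


class TestComputeTPM:
    def test_hand_evaluated(self):
        # rates (10/100, 10/200) = (0.1, 0.05) -> shares (2/3, 1/3) of 1e6
        out = compute_tpm([10, 10], [100, 200])
        assert out == pytest.approx([666666.6666666667, 333333.3333333333])

    def test_single_transcript(self):
        assert compute_tpm([3], [250]) == pytest.approx([1e6])

    def test_zero_count_entry(self):
        out = compute_tpm([0, 5], [100, 100])
        assert out[0] == 0.0
        assert out[1] == pytest.approx(1e6)

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError, match="all counts are zero"):
            compute_tpm([0, 0], [100, 100])

    def test_non_positive_eff_length_error(self):
        with pytest.raises(ValueError, match="> 0"):
            compute_tpm([1, 1], [100, 0])

    @settings(max_examples=100, deadline=None)
    @given(
        counts=st.lists(st.floats(0, 1e6), min_size=1, max_size=50),
        seed=st.integers(0, 2**31),
    )
    def test_sums_to_one_million(self, counts, seed):
        rng = np.random.default_rng(seed)
        lengths = rng.uniform(10, 1e4, len(counts))
        counts = [0.0 if c < 1e-6 else c for c in counts]  # avoid subnormal underflow
        if sum(counts) == 0:
            counts[0] = 1.0
        out = compute_tpm(counts, lengths)
        assert out.sum() == pytest.approx(1e6, rel=1e-6)


class TestComputeFPKM:
    def test_hand_evaluated(self):
        # 10 fragments / 1 kb / (10 * 1e-6 million fragments)
        assert compute_fpkm([10], [1000]) == pytest.approx([1e6])

    def test_zero_entry(self):
        out = compute_fpkm([0, 8], [100, 200])
        assert out[0] == 0.0

    def test_zero_total_error(self):
        with pytest.raises(ValueError, match="zero total"):
            compute_fpkm([0, 0], [100, 200])

    @settings(max_examples=50, deadline=None)
    @given(seed=st.integers(0, 2**31), n=st.integers(1, 40))
    def test_tpm_fpkm_identity(self, seed, n):
        rng = np.random.default_rng(seed)
        counts = rng.uniform(0, 1e4, n)
        counts[0] += 1.0
        lengths = rng.uniform(50, 5e3, n)
        fpkm = compute_fpkm(counts, lengths)
        tpm = compute_tpm(counts, lengths)
        np.testing.assert_allclose(tpm, fpkm / fpkm.sum() * 1e6, rtol=1e-9)


class TestAggregate:
    def test_additive(self):
        recs = [
            AbundanceRecord("t1", 100, 90, 1, 5.0),
            AbundanceRecord("t2", 100, 90, 1, 7.0),
        ]
        out = aggregate_to_genes(recs, {"t1": "g", "t2": "g"})
        assert out["g"] == pytest.approx(12.0)

    def test_one_to_one_identity(self):
        recs = [AbundanceRecord(f"t{i}", 100, 90, 1, float(i)) for i in range(5)]
        out = aggregate_to_genes(recs, {f"t{i}": f"g{i}" for i in range(5)})
        for i in range(5):
            assert out[f"g{i}"] == float(i)

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(10)]
        t2g = {f"t{i}": genes[rng.integers(0, 10)] for i in range(100)}
        recs = [
            AbundanceRecord(f"t{i}", 100, 90, 1, float(rng.uniform(0, 100)))
            for i in range(100)
        ]
        out = aggregate_to_genes(recs, t2g)
        oracle = (
            pd.DataFrame({"gene": [t2g[r.transcript_id] for r in recs], "tpm": [r.tpm for r in recs]})
            .groupby("gene")["tpm"]
            .sum()
        )
        assert set(out.index) == set(oracle.index)
        for g in oracle.index:
            assert out[g] == pytest.approx(oracle[g])

    def test_unmapped_dropped_conserves_rest(self):
        recs = [
            AbundanceRecord("t1", 100, 90, 1, 5.0),
            AbundanceRecord("tx", 100, 90, 1, 3.0),  # unmapped
        ]
        out = aggregate_to_genes(recs, {"t1": "g"})
        assert out.sum() == pytest.approx(5.0)

    def test_empty_map_error(self):
        recs = [AbundanceRecord("t1", 100, 90, 1, 5.0)]
        with pytest.raises(ValueError, match="empty"):
            aggregate_to_genes(recs, {})


class TestAssemble:
    def test_two_samples_identical_genes(self):
        metas = [SampleMeta("a", "transgenic", "DN1", 1), SampleMeta("b", "wildtype", "DN1", 1)]
        m = assemble_matrix(
            {"a": pd.Series({"g1": 1.0, "g2": 2.0}), "b": pd.Series({"g1": 3.0, "g2": 4.0})},
            metas,
        )
        assert m.values.shape == (2, 2)
        assert m.sample_ids == ["a", "b"]
        assert m.values.at["g2", "b"] == 4.0

    def test_missing_gene_zero_filled_with_warning(self):
        metas = [SampleMeta("a", "transgenic", "DN1", 1), SampleMeta("b", "wildtype", "DN1", 1)]
        with pytest.warns(UserWarning, match="zero-filled"):
            m = assemble_matrix(
                {"a": pd.Series({"g1": 1.0}), "b": pd.Series({"g2": 2.0})}, metas
            )
        assert m.values.at["g1", "b"] == 0.0
        assert m.values.at["g2", "a"] == 0.0

    def test_duplicate_sample_id_error(self):
        metas = [SampleMeta("a", "transgenic", "DN1", 1), SampleMeta("a", "wildtype", "DN1", 1)]
        with pytest.raises(ValueError, match="duplicate sample_id"):
            assemble_matrix({"a": pd.Series({"g1": 1.0})}, metas)


class TestGroupMean:
    def test_two_replicates(self):
        metas = [
            SampleMeta("a", "transgenic", "DN1", 1),
            SampleMeta("b", "transgenic", "DN1", 2),
        ]
        m = make_matrix({"g": [2.0, 4.0]}, metas)
        assert group_mean(m, "transgenic", "DN1")["g"] == pytest.approx(3.0)

    def test_single_replicate_identity(self, toy_matrix):
        assert group_mean(toy_matrix, "transgenic", "DN1")["G1"] == 25.0

    def test_three_random_replicates_vs_sum_over_three(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 100, 3)
        metas = [SampleMeta(f"s{i}", "wildtype", "DN2", i + 1) for i in range(3)]
        m = make_matrix({"g": list(vals)}, metas)
        assert group_mean(m, "wildtype", "DN2")["g"] == pytest.approx(vals.sum() / 3)

    def test_no_matching_samples(self):
        m = make_matrix({"g": [1.0]}, [SampleMeta("s", "transgenic", "DN1", 1)])
        with pytest.raises(ValueError, match="no samples"):
            group_mean(m, "wildtype", "DN1")


class TestSampleMeta:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"genotype": "mutant"},
            {"stage": "DN5"},
            {"replicate": 0},
            {"sample_id": ""},
        ],
    )
    def test_invalid_fields(self, kwargs):
        base = {"sample_id": "s", "genotype": "transgenic", "stage": "DN1", "replicate": 1}
        with pytest.raises(ValueError):
            SampleMeta(**{**base, **kwargs})


class TestSheetAndMatrixIO:
    def test_sample_sheet_roundtrip_and_relative_paths(self, tmp_path):
        sheet = tmp_path / "samples.tsv"
        sheet.write_text(
            "sample_id\tgenotype\tstage\treplicate\tpath\n"
            "a\ttransgenic\tDN1\t1\ta.tsv\n"
            "b\twildtype\tDN1\t1\tsub/b.tsv\n"
        )
        rows = read_sample_sheet(sheet)
        assert rows[0][0].sample_id == "a"
        assert rows[0][1] == tmp_path / "a.tsv"
        assert rows[1][1] == tmp_path / "sub" / "b.tsv"

    def test_sample_sheet_duplicate_triple(self, tmp_path):
        sheet = tmp_path / "samples.tsv"
        sheet.write_text(
            "sample_id\tgenotype\tstage\treplicate\tpath\n"
            "a\ttransgenic\tDN1\t1\ta.tsv\n"
            "b\ttransgenic\tDN1\t1\tb.tsv\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            read_sample_sheet(sheet)

    def test_t2g_bad_header(self, tmp_path):
        p = tmp_path / "t2g.tsv"
        p.write_text("tx\tgene\nt1\tg1\n")
        with pytest.raises(AbundanceFormatError, match="header"):
            read_t2g(p)

    def test_matrix_roundtrip(self, tmp_path, toy_matrix):
        p = tmp_path / "m.tsv"
        write_matrix(toy_matrix, p)
        back = read_matrix(p)
        assert back.unit == toy_matrix.unit
        assert back.samples == toy_matrix.samples
        pd.testing.assert_frame_equal(back.values, toy_matrix.values)


class TestMatrixInvariants:
    def test_negative_entries_rejected(self, metas8):
        with pytest.raises(ValueError, match="negative"):
            make_matrix({"g": [-1.0] + [0.0] * 7}, metas8)

    def test_duplicate_gene_rejected(self, metas8):
        df = pd.DataFrame(
            np.ones((2, 8)), index=["g", "g"], columns=[m.sample_id for m in metas8]
        )
        from surfdbm.expression import ExpressionMatrix

        with pytest.raises(ValueError, match="duplicate gene"):
            ExpressionMatrix(values=df, samples=metas8)

    def test_column_order_enforced(self, metas8):
        df = pd.DataFrame(
            np.ones((1, 8)), index=["g"], columns=[m.sample_id for m in reversed(metas8)]
        )
        from surfdbm.expression import ExpressionMatrix

        with pytest.raises(ValueError, match="column"):
            ExpressionMatrix(values=df, samples=metas8)
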