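import numpy as np
import pandas as pd
import pytest

from rifseq.errors import ValidationError
from rifseq.io import CountMatrix
from rifseq.normalization import compute_fpkm, normalize, tmm_factors


def tmm_oracle(mat, lib, ref_idx, trim_m=0.30, trim_a=0.05):
    """Independent brute-force TMM: explicit loops, sort-based average ranks."""

    def avg_ranks(v):
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            for k in range(i, j + 1):
                ranks[order[k]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    factors = []
    for s in range(mat.shape[1]):
        ms, ws, as_ = [], [], []
        for g in range(mat.shape[0]):
            o, r = mat[g, s], mat[g, ref_idx]
            if o > 0 and r > 0:
                po, pr = o / lib[s], r / lib[ref_idx]
                ms.append(np.log2(po / pr))
                as_.append(0.5 * np.log2(po * pr))
                ws.append((lib[s] - o) / (lib[s] * o) + (lib[ref_idx] - r) / (lib[ref_idx] * r))
        ms, ws, as_ = map(np.array, (ms, ws, as_))
        if np.max(np.abs(ms)) < 1e-6:
            factors.append(1.0)
            continue
        n = len(ms)
        rm, ra = avg_ranks(ms), avg_ranks(as_)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n - np.floor(n * trim_a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        factors.append(2.0 ** (np.sum(ms[keep] / ws[keep]) / np.sum(1.0 / ws[keep])))
    factors = np.array(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestFPKM:
    def test_formula_pins_simple_cell(self, make_norm_factory):
        # count 10, length 1000 bp, library 1e6 -> 10 * 1e9 / (1e6 * 1e3) = 10
        counts = CountMatrix(pd.DataFrame(
            {"s1": [10, 999_990], "s2": [10, 999_990]},
            index=["g1", "g2"],
        ))
        meta = pd.DataFrame({"length_bp": [1000, 1000]},
                            index=pd.Index(["g1", "g2"], name="gene_id"))
        norm = compute_fpkm(counts, meta)
        assert norm.lib_size["s1"] == 1_000_000
        assert norm.fpkm.loc["g1", "s1"] == pytest.approx(10.0)

    def test_zero_count_gives_zero_fpkm(self, small_counts, small_meta):
        norm = compute_fpkm(small_counts, small_meta)
        zeros = small_counts.counts.to_numpy() == 0
        assert np.all((norm.fpkm.to_numpy() == 0) == zeros)

    def test_matches_cell_by_cell_formula(self, rng):
        counts = CountMatrix(pd.DataFrame(
            rng.integers(0, 500, (50, 6)) + 1,  # +1 keeps libraries positive
            index=[f"g{i}" for i in range(50)],
            columns=[f"s{j}" for j in range(6)],
        ))
        lengths = rng.integers(200, 5000, 50)
        meta = pd.DataFrame({"length_bp": lengths},
                            index=pd.Index(counts.gene_ids, name="gene_id"))
        norm = compute_fpkm(counts, meta)
        lib = counts.counts.sum(axis=0).to_numpy()
        for g in range(50):
            for s in range(6):
                expect = counts.counts.iat[g, s] * 1e9 / (lib[s] * lengths[g])
                assert norm.fpkm.iat[g, s] == pytest.approx(expect, rel=1e-12)
        assert np.allclose(norm.log_expr, np.log2(norm.fpkm + 1))

    def test_length_scaling_divides_row(self, small_counts, small_meta):
        norm = compute_fpkm(small_counts, small_meta)
        meta3 = small_meta.copy()
        meta3.loc["g3", "length_bp"] *= 4
        norm3 = compute_fpkm(small_counts, meta3)
        assert np.allclose(norm3.fpkm.loc["g3"], norm.fpkm.loc["g3"] / 4)
        assert np.allclose(norm3.fpkm.drop("g3"), norm.fpkm.drop("g3"))

    def test_zero_library_rejected(self, small_meta):
        counts = CountMatrix(pd.DataFrame(
            {"s1": [1, 2, 3, 4], "s2": [0, 0, 0, 0]},
            index=small_meta.index,
        ))
        with pytest.raises(ValidationError, match="s2"):
            compute_fpkm(counts, small_meta)


class TestTMM:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.integers(1, 300, 100)
        counts = CountMatrix(pd.DataFrame(
            {f"s{j}": col for j in range(4)}, index=[f"g{i}" for i in range(100)],
        ))
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_pure_depth_change_absorbed_by_library_size(self, rng):
        col = rng.integers(1, 300, 200)
        counts = CountMatrix(pd.DataFrame(
            {"s1": col, "s2": col * 2, "s3": col, "s4": col * 3},
            index=[f"g{i}" for i in range(200)],
        ))
        assert np.allclose(tmm_factors(counts), 1.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            mat = rng.poisson(rng.lognormal(3, 1, 200)[:, None] *
                              rng.uniform(0.5, 2.0, 4)[None, :])
            mat[0] += 1  # avoid an all-zero reference pathology
            counts = CountMatrix(pd.DataFrame(
                mat, index=[f"g{i}" for i in range(200)],
                columns=[f"s{j}" for j in range(4)],
            ))
            got = tmm_factors(counts, ref_sample="s1").to_numpy()
            lib = mat.sum(axis=0)
            want = tmm_oracle(mat.astype(float), lib.astype(float), counts.sample_ids.index("s1"))
            assert np.allclose(got, want, rtol=1e-10)

    def test_global_rescaling_invariance(self, rng):
        mat = rng.poisson(rng.lognormal(3, 1, 150)[:, None] *
                          rng.uniform(0.5, 2.0, 4)[None, :]) + 1
        cm = CountMatrix(pd.DataFrame(mat, index=[f"g{i}" for i in range(150)],
                                      columns=list("abcd")))
        cm5 = CountMatrix(pd.DataFrame(mat * 5, index=cm.gene_ids, columns=list("abcd")))
        assert np.allclose(tmm_factors(cm, ref_sample="b"),
                           tmm_factors(cm5, ref_sample="b"), rtol=1e-6)

    def test_sample_permutation_permutes_factors(self, rng):
        mat = rng.poisson(rng.lognormal(3, 1, 150)[:, None] *
                          rng.uniform(0.5, 2.0, 5)[None, :]) + 1
        df = pd.DataFrame(mat, index=[f"g{i}" for i in range(150)],
                          columns=list("abcde"))
        f = tmm_factors(CountMatrix(df), ref_sample="c")
        perm = list("dbeac")
        fp = tmm_factors(CountMatrix(df[perm]), ref_sample="c")
        assert np.allclose(f.loc[perm].to_numpy(), fp.to_numpy(), rtol=1e-12)

    def test_factors_have_unit_geometric_mean(self, rng):
        mat = rng.poisson(rng.lognormal(3, 1.5, 300)[:, None] *
                          rng.uniform(0.3, 3.0, 6)[None, :]) + 1
        f = tmm_factors(CountMatrix(pd.DataFrame(
            mat, index=[f"g{i}" for i in range(300)], columns=list("abcdef"))))
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_support_rejected(self):
        counts = CountMatrix(pd.DataFrame(
            {"s1": [5, 5, 0, 0], "s2": [0, 0, 5, 5]}, index=list("wxyz")))
        with pytest.raises(ValidationError, match="no nonzero genes"):
            tmm_factors(counts, ref_sample="s1")


def test_normalize_composes_fpkm_and_tmm(small_counts, small_meta):
    norm = normalize(small_counts, small_meta, use_tmm=True)
    assert np.exp(np.mean(np.log(norm.tmm_factor))) == pytest.approx(1.0)
    plain = normalize(small_counts, small_meta, use_tmm=False)
    assert np.allclose(plain.tmm_factor, 1.0)
    pd.testing.assert_frame_equal(norm.fpkm, plain.fpkm)
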