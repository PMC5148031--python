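import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rifseq.de import DEConfig, bh_fdr, call_de, estimate_dispersion, exact_nb_test
from rifseq.errors import ValidationError
from rifseq.io import CountMatrix, SampleDesign


def exact_test_oracle(s1, s2, n1, n2, dispersion):
    """Independent enumeration of conditional split probabilities."""
    s1, s2 = int(round(s1)), int(round(s2))
    s = s1 + s2
    if s == 0:
        return 1.0
    x = np.arange(s + 1)
    if dispersion == 0:
        probs = stats.binom.pmf(x, s, n1 / (n1 + n2))
    else:
        mu = s / (n1 + n2)
        size1, size2 = n1 / dispersion, n2 / dispersion
        probs = stats.nbinom.pmf(x, size1, size1 / (size1 + n1 * mu)) * \
            stats.nbinom.pmf(s - x, size2, size2 / (size2 + n2 * mu))
    p_obs = probs[s1]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum() / probs.sum())


def bh_oracle(p):
    """Definitional two-pass BH step-up."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        out[i] = running
    return out


def _nb_counts(rng, n_genes, n_samples, dispersion, mean_low=20, mean_high=400):
    mu = rng.uniform(mean_low, mean_high, n_genes)[:, None] * np.ones(n_samples)
    if dispersion == 0:
        return rng.poisson(mu)
    r = 1 / dispersion
    return rng.negative_binomial(r, r / (r + mu))


def _as_cm(mat):
    return CountMatrix(pd.DataFrame(
        mat, index=[f"g{i}" for i in range(mat.shape[0])],
        columns=[f"s{j}" for j in range(mat.shape[1])],
    ))


class TestDispersion:
    def test_poisson_counts_estimate_near_zero(self, rng):
        cm = _as_cm(_nb_counts(rng, 1500, 12, 0.0))
        lib = cm.lib_sizes().astype(float)
        est = estimate_dispersion(cm, lib, (cm.sample_ids[:6], cm.sample_ids[6:]))
        assert est == pytest.approx(0.0, abs=0.01)

    def test_nb_dispersion_recovery(self, rng):
        cm = _as_cm(_nb_counts(rng, 2000, 12, 0.2))
        lib = cm.lib_sizes().astype(float)
        est = estimate_dispersion(cm, lib, (cm.sample_ids[:6], cm.sample_ids[6:]))
        assert est == pytest.approx(0.2, abs=0.05)

    def test_duplicated_samples_have_zero_dispersion(self, rng):
        x = rng.integers(10, 200, 50)
        y = rng.integers(10, 200, 50)
        mat = np.column_stack([x, x, x, y, y, y])
        cm = _as_cm(mat)
        lib = cm.lib_sizes().astype(float)
        est = estimate_dispersion(cm, lib, (cm.sample_ids[:3], cm.sample_ids[3:]))
        assert est == 0.0

    def test_all_zero_matrix_rejected(self):
        cm = pd.DataFrame(np.zeros((5, 6), dtype=int),
                          index=[f"g{i}" for i in range(5)],
                          columns=[f"s{j}" for j in range(6)])
        with pytest.raises(ValidationError, match="all-zero"):
            estimate_dispersion(cm, np.ones(6), (list(cm.columns[:3]), list(cm.columns[3:])))

    def test_tagwise_shrinks_toward_common(self, rng):
        cm = _as_cm(_nb_counts(rng, 300, 12, 0.15))
        lib = cm.lib_sizes().astype(float)
        groups = (cm.sample_ids[:6], cm.sample_ids[6:])
        common = estimate_dispersion(cm, lib, groups, mode="common")
        tag = estimate_dispersion(cm, lib, groups, mode="tagwise")
        assert tag.shape == (300,)
        # shrinkage keeps the per-gene spread centered near the common value
        assert abs(np.median(tag) - common) < 0.1


class TestExactTest:
    def test_binomial_limit(self):
        for s1, s2, n1, n2 in [(5, 5, 3, 3), (2, 8, 3, 3), (0, 7, 4, 4), (9, 3, 2, 4)]:
            want = stats.binomtest(s1, s1 + s2, n1 / (n1 + n2)).pvalue
            assert exact_nb_test(s1, s2, n1, n2, 0.0) == pytest.approx(want, abs=1e-12)

    def test_equal_counts_give_p_one(self):
        assert exact_nb_test(30, 30, 3, 3, 0.1) == pytest.approx(1.0)
        assert exact_nb_test(0, 0, 3, 3, 0.2) == 1.0

    def test_matches_enumeration_oracle_small_sums(self, rng):
        for _ in range(60):
            s = int(rng.integers(1, 31))
            s1 = int(rng.integers(0, s + 1))
            n1, n2 = rng.integers(2, 7, 2)
            disp = float(rng.uniform(0.0, 0.8))
            got = exact_nb_test(s1, s - s1, int(n1), int(n2), disp)
            want = exact_test_oracle(s1, s - s1, int(n1), int(n2), disp)
            assert got == pytest.approx(want, abs=1e-9)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValidationError, match="dispersion"):
            exact_nb_test(5, 5, 3, 3, -0.1)


class TestBH:
    def test_step_up_forces_ties(self):
        got = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_empty_input(self):
        assert bh_fdr(np.array([])).size == 0

    def test_matches_definitional_oracle(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1, int(rng.integers(1, 60)))
            assert np.allclose(bh_fdr(p), bh_oracle(p), rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr(np.array([0.5, 0.0]))


class TestCallDE:
    def _filter_fixture(self, make_norm):
        samples = ["a1", "a2", "a3", "b1", "b2", "b3"]
        # FPKM chosen per gene; counts carry the statistical evidence
        fpkm = pd.DataFrame(
            {
                "low_expr": [0.4, 0.4, 0.4, 0.3, 0.3, 0.3],
                "low_fc": [1.49, 1.49, 1.49, 1.0, 1.0, 1.0],
                "high_p": [2.0, 2.0, 2.0, 1.0, 1.0, 1.0],
                "hit": [10.0, 10.0, 10.0, 1.0, 1.0, 1.0],
            },
            index=samples,
        ).T
        counts = CountMatrix(pd.DataFrame(
            {
                "low_expr": [100, 110, 90, 500, 480, 520],
                "low_fc": [500, 520, 480, 100, 90, 110],
                "high_p": [200, 200, 200, 200, 200, 200],
                "hit": [1000, 980, 1020, 100, 110, 90],
            },
            index=samples,
        ).T)
        design = SampleDesign(
            pd.DataFrame({"sample_id": samples,
                          "condition": ["A"] * 3 + ["B"] * 3}),
            ("A", "B"),
        )
        return counts, make_norm(fpkm), design

    def test_filters_applied_independently(self, make_norm_factory):
        counts, norm, design = self._filter_fixture(make_norm_factory)
        res = call_de(counts, norm, design, DEConfig(), dispersion=0.0).set_index("gene_id")
        # below 0.5 FPKM in both groups: not expressed, never DE, no p computed
        assert not res.loc["low_expr", "expressed"]
        assert not res.loc["low_expr", "de"]
        assert np.isnan(res.loc["low_expr", "p"])
        # expressed but FC 1.485 < 1.5: not DE despite tiny p
        assert res.loc["low_fc", "expressed"]
        assert res.loc["low_fc", "fc"] < 1.5
        assert res.loc["low_fc", "p"] < 1e-6
        assert not res.loc["low_fc", "de"]
        # expressed, FC ~2, but p = 1: not DE
        assert res.loc["high_p", "fc"] >= 1.5
        assert res.loc["high_p", "p"] == pytest.approx(1.0)
        assert not res.loc["high_p", "de"]
        # everything passes
        assert res.loc["hit", "de"]
        assert res.loc["hit", "direction"] == "up_in_A"

    def test_contrast_swap_flips_direction_only(self, make_norm_factory):
        counts, norm, design = self._filter_fixture(make_norm_factory)
        flipped = SampleDesign(design.table, ("B", "A"))
        a = call_de(counts, norm, design, DEConfig(), dispersion=0.0)
        b = call_de(counts, norm, flipped, DEConfig(), dispersion=0.0)
        assert np.allclose(a["fc"], b["fc"])
        assert np.allclose(a["p"], b["p"], equal_nan=True)
        assert np.allclose(a["fdr"], b["fdr"], equal_nan=True)
        assert (a["de"] == b["de"]).all()
        flip = {"up_in_A": "up_in_B", "up_in_B": "up_in_A"}
        assert (b["direction"] == a["direction"].map(flip)).all()

    def test_tightening_thresholds_never_adds_de(self, make_norm_factory):
        counts, norm, design = self._filter_fixture(make_norm_factory)
        loose = call_de(counts, norm, design,
                        DEConfig(min_group_fpkm=0.2, min_fc=1.2, max_p=0.05),
                        dispersion=0.0)
        tight = call_de(counts, norm, design, DEConfig(), dispersion=0.0)
        assert set(tight.loc[tight["de"], "gene_id"]) <= set(loose.loc[loose["de"], "gene_id"])

    def test_fdr_monotone_over_sorted_p(self, make_norm_factory):
        counts, norm, design = self._filter_fixture(make_norm_factory)
        res = call_de(counts, norm, design, DEConfig(), dispersion=0.0)
        sub = res.dropna(subset=["p"]).sort_values("p")
        assert (np.diff(sub["fdr"]) >= -1e-15).all()
        assert (sub["fdr"] >= sub["p"] - 1e-15).all()
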