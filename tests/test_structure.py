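import numpy as np
import pandas as pd
import pytest

import pooldiv as pv
from pooldiv.stats import FrequencyMatrix
from pooldiv.structure import amova, amova_permutation, pca


def amova_ss_oracle(x, acc, ct):
    """Brute-force sums of squares from explicit group means (worked
    independently of the implementation)."""
    x = np.asarray(x, dtype=float)
    acc = np.asarray(acc)
    ct = np.asarray(ct)
    grand = x.mean(axis=0)
    ss_ct = sum(
        (ct == c).sum() * ((x[ct == c].mean(axis=0) - grand) ** 2).sum()
        for c in dict.fromkeys(ct)
    )
    ss_acc = sum(
        (acc == a).sum()
        * ((x[acc == a].mean(axis=0) - x[ct == ct[acc == a][0]].mean(axis=0)) ** 2).sum()
        for a in dict.fromkeys(acc)
    )
    ss_within = sum(
        ((x[acc == a] - x[acc == a].mean(axis=0)) ** 2).sum() for a in dict.fromkeys(acc)
    )
    return ss_ct, ss_acc, ss_within


def make_hierarchy(acc_ct):
    return pv.LineageHierarchy("sp", {a: a for a in acc_ct}, dict(acc_ct))


class TestPca:
    def test_two_centroid_rank_one_structure(self):
        """Duplicated cluster centroids are rank-1 after centering: PC1
        explains all variance and separates the clusters."""
        c1 = np.array([0.1, 0.9, 0.5, 0.2])
        c2 = np.array([0.9, 0.1, 0.5, 0.8])
        q = np.column_stack([c1, c1, c2, c2])  # sites x pools
        fm = FrequencyMatrix(q, ["a1", "a2", "b1", "b2"])
        res = pca(fm)
        assert res.variance_explained[0] == pytest.approx(1.0)
        s = res.scores["PC1"]
        assert np.sign(s["a1"]) == np.sign(s["a2"]) != np.sign(s["b1"])

    def test_scores_have_zero_mean_when_centered(self, rng):
        fm = FrequencyMatrix(rng.random((100, 6)), list("abcdef"))
        res = pca(fm)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0.0, atol=1e-10)

    def test_reconstruction_identity(self, rng):
        """U S Vt rebuilt from all components equals the centered input."""
        q = rng.random((200, 8))
        fm = FrequencyMatrix(q, [f"p{i}" for i in range(8)])
        res = pca(fm)
        x = q.T - q.T.mean(axis=0, keepdims=True)
        rebuilt = res.scores.to_numpy() @ res.loadings
        assert np.linalg.norm(rebuilt - x) < 1e-8

    def test_variance_fractions_valid_and_order_invariant(self, rng):
        q = rng.random((150, 5))
        fm = FrequencyMatrix(q, list("abcde"))
        res = pca(fm)
        assert res.variance_explained.sum() <= 1 + 1e-9
        perm = [3, 1, 4, 0, 2]
        fm2 = FrequencyMatrix(q[:, perm], [list("abcde")[i] for i in perm])
        res2 = pca(fm2)
        np.testing.assert_allclose(res.variance_explained, res2.variance_explained, atol=1e-10)

    def test_chromosome_scope_restricts_sites(self, rng):
        q = rng.random((60, 4))
        vt = pd.DataFrame({"chrom": ["Chr1"] * 40 + ["Chr2"] * 20,
                           "pos": range(1, 61)})
        fm = FrequencyMatrix(q, list("abcd"))
        res = pca(fm, vt=vt, chromosome="Chr2")
        assert res.n_sites_used == 20 and res.scope == "Chr2"

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            pca(FrequencyMatrix(np.random.rand(5, 1), ["a"]))


class TestAmova:
    def test_all_pools_identical_gives_zero_components(self):
        q = np.full((3, 4), 0.4)  # 3 sites x 4 identical pools
        h = make_hierarchy({"a1": "X", "a2": "X", "b1": "Y", "b2": "Y"})
        res = amova(FrequencyMatrix(q, ["a1", "a2", "b1", "b2"]), h)
        assert all(v == 0 for v in res.sigma.values())

    def test_hand_fixture_matches_ss_oracle(self):
        """2 crop types x 2 accessions at 3 loci: sums of squares from the
        implementation equal the explicit group-mean decomposition, and
        the variance components follow from the mean squares (one pool
        per accession, so the within stratum is 0 with df 0)."""
        x = np.array(
            [[0.1, 0.2, 0.3],
             [0.2, 0.1, 0.4],
             [0.8, 0.9, 0.6],
             [0.7, 0.8, 0.7]]
        )  # pools x loci
        acc = ["a1", "a2", "b1", "b2"]
        ct = ["X", "X", "Y", "Y"]
        h = make_hierarchy(dict(zip(acc, ct)))
        fm = FrequencyMatrix(x.T, acc)
        res = amova(fm, h)
        ss_ct, ss_acc, ss_within = amova_ss_oracle(x, acc, ct)
        assert res.ss["among_crop_types"] == pytest.approx(ss_ct, abs=1e-10)
        assert res.ss["among_accessions_within_crop_types"] == pytest.approx(ss_acc, abs=1e-10)
        assert res.ss["within_accessions"] == pytest.approx(ss_within, abs=1e-10)
        # balanced design: n' = 1, n''' = 2; sigma from mean squares
        ms_ct = ss_ct / 1
        ms_acc = ss_acc / 2
        sigma_acc = ms_acc  # (MS_acc - 0) / 1
        sigma_ct = (ms_ct - sigma_acc) / 2
        assert res.sigma["among_accessions_within_crop_types"] == pytest.approx(sigma_acc, abs=1e-10)
        assert res.sigma["among_crop_types"] == pytest.approx(max(sigma_ct, 0), abs=1e-10)
        assert res.df == {"among_crop_types": 1,
                          "among_accessions_within_crop_types": 2,
                          "within_accessions": 0}
        assert sum(res.percent.values()) == pytest.approx(100.0)

    def test_random_fixtures_match_oracle(self, rng):
        """SS decomposition equals the brute-force oracle on random
        6-pool fixtures (including an unbalanced 4+2 design)."""
        for _ in range(10):
            x = rng.random((6, 5))
            acc = [f"a{i}" for i in range(6)]
            ct = ["X", "X", "X", "X", "Y", "Y"]
            h = make_hierarchy(dict(zip(acc, ct)))
            res = amova(FrequencyMatrix(x.T, acc), h)
            ss = amova_ss_oracle(x, acc, ct)
            for got, want in zip(
                (res.ss["among_crop_types"],
                 res.ss["among_accessions_within_crop_types"],
                 res.ss["within_accessions"]),
                ss,
            ):
                assert got == pytest.approx(want, abs=1e-10)
            total_ss = ((x - x.mean(axis=0)) ** 2).sum()
            assert sum(res.ss.values()) == pytest.approx(total_ss, abs=1e-10)

    def test_multiple_pools_per_accession_within_component(self, rng):
        """With replicate pools inside accessions the within stratum has
        df > 0 and the three components still close against the oracle."""
        x = rng.random((8, 4))
        acc = ["a1", "a1", "a2", "a2", "b1", "b1", "b2", "b2"]
        ct = ["X", "X", "X", "X", "Y", "Y", "Y", "Y"]
        h = pv.LineageHierarchy(
            "sp",
            {f"p{i}": a for i, a in enumerate(acc)},
            {"a1": "X", "a2": "X", "b1": "Y", "b2": "Y"},
        )
        fm = FrequencyMatrix(x.T, [f"p{i}" for i in range(8)])
        res = amova(fm, h)
        ss = amova_ss_oracle(x, acc, ct)
        assert res.df["within_accessions"] == 4
        for got, want in zip(
            (res.ss["among_crop_types"], res.ss["among_accessions_within_crop_types"],
             res.ss["within_accessions"]), ss):
            assert got == pytest.approx(want, abs=1e-10)

    def test_among_croptype_percent_monotone_in_f_ct(self):
        """Stronger crop-type drift must raise the among-crop-type percent
        (paired seeds, 2 crop types x 6 accessions)."""
        for seed in range(5):
            pcts = []
            for f_ct in (0.01, 0.2):
                p = pv.SimParams(n_crop_types=2, accessions_per_type=6, n_loci=1500,
                                 f_ct=f_ct, f_acc=0.01, error_rate=0.0, seed=seed)
                t = pv.simulate_frequencies(p)
                _, acm = pv.sample_pool_counts(t, p, seed=seed + 100)
                fm = pv.allele_frequency(acm, min_depth=15)
                res = amova(fm, t.hierarchy)
                pcts.append(res.percent["among_crop_types"])
            assert pcts[1] > pcts[0]


class TestAmovaPermutation:
    @pytest.fixture
    def structured_fm(self):
        rng = np.random.default_rng(5)
        base = rng.random(400)
        shift = np.where(rng.random(400) < 0.5, 0.35, -0.35)
        cols = {}
        for i in range(4):
            cols[f"x{i}"] = np.clip(base + rng.normal(0, 0.01, 400), 0, 1)
        for i in range(4):
            cols[f"y{i}"] = np.clip(base + shift + rng.normal(0, 0.01, 400), 0, 1)
        q = np.column_stack(list(cols.values()))
        h = make_hierarchy({c: ("X" if c.startswith("x") else "Y") for c in cols})
        return FrequencyMatrix(q, list(cols)), h

    def test_perfect_separation_attains_minimal_p(self, structured_fm):
        fm, h = structured_fm
        res = amova_permutation(fm, h, n_perm=19, seed=1)
        assert res.p_value <= 3 / 20  # near the attainable floor of 1/20

    def test_seeded_reproducibility(self, structured_fm):
        fm, h = structured_fm
        a = amova_permutation(fm, h, n_perm=29, seed=7)
        b = amova_permutation(fm, h, n_perm=29, seed=7)
        assert a.p_value == b.p_value

    def test_no_structure_gives_large_p(self):
        """Without crop-type drift the permutation p-value should not be
        extreme (checked over a few seeds)."""
        big = 0
        for seed in range(5):
            p = pv.SimParams(n_crop_types=2, accessions_per_type=4, n_loci=400,
                             f_ct=0.0, f_acc=0.05, error_rate=0.0, seed=seed)
            t = pv.simulate_frequencies(p)
            _, acm = pv.sample_pool_counts(t, p, seed=seed + 50)
            fm = pv.allele_frequency(acm, min_depth=15)
            res = amova_permutation(fm, t.hierarchy, n_perm=39, seed=seed)
            if res.p_value > 0.05:
                big += 1
        assert big >= 3

    def test_invalid_n_perm_rejected(self, structured_fm):
        fm, h = structured_fm
        with pytest.raises(ValueError):
            amova_permutation(fm, h, n_perm=0)
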