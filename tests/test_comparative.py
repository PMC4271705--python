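"""Cross-nutrient regressions, phylogenetic signal and the equivalence fit."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from rootforage import (
    DegenerateError,
    InsufficientDataError,
    UptakeKinetics,
    blomberg_k,
    equivalence_fit,
    pair_traits,
    regress,
)
from rootforage.comparative import PairedTraitSet, UptakeCurveModel, tree_covariance
from rootforage.fixtures import gen_bm_traits, gen_tree

from conftest import record


def translated_frame(rows):
    """rows: (species, nutrient, basis, a) -> minimal translated table."""
    df = pd.DataFrame(rows, columns=["species", "nutrient", "basis", "a"])
    df["h"] = 1.0
    df["v_max"] = 1.0 / df["h"]
    df["k_m"] = 1.0 / (df["a"] * df["h"])
    df["study_id"] = [f"s{i}" for i in range(len(df))]
    return df


class TestPairTraits:
    def test_single_nutrient_species_excluded(self):
        df = translated_frame([
            ("A", "NO3", "dry", 1.0), ("A", "NH4", "dry", 2.0),
            ("B", "NO3", "dry", 1.0), ("B", "NH4", "dry", 1.5),
            ("C", "NO3", "dry", 1.0), ("C", "NH4", "dry", 0.5),
            ("D", "NO3", "dry", 9.0),  # NO3 only
        ])
        pairs = pair_traits(df, "a")
        assert pairs.n == 3
        assert "D" not in pairs.species

    def test_multi_study_averaged_before_transform(self):
        df = translated_frame([
            ("A", "NO3", "dry", 1.0), ("A", "NO3", "dry", 3.0),
            ("A", "NH4", "dry", 2.0),
            ("B", "NO3", "dry", 1.0), ("B", "NH4", "dry", 1.0),
            ("C", "NO3", "dry", 4.0), ("C", "NH4", "dry", 1.0),
        ])
        pairs = pair_traits(df, "a")
        x_a = pairs.x[list(pairs.species).index("A")]
        assert x_a == pytest.approx(np.log1p(2.0), rel=1e-14)  # mean(1,3) then ln(x+1)

    def test_insufficient_pairs_raise(self):
        df = translated_frame([
            ("A", "NO3", "dry", 1.0), ("A", "NH4", "dry", 2.0),
            ("B", "NO3", "dry", 1.0), ("B", "NH4", "dry", 1.5),
        ])
        with pytest.raises(InsufficientDataError):
            pair_traits(df, "a")

    def test_synthetic_default_yields_28_pairs(self, synthetic_translated):
        pairs = pair_traits(synthetic_translated, "a")
        assert pairs.n == 28
        assert regress(pairs).df == (1, 26)


class TestRegress:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        p = PairedTraitSet("a", tuple("abcde"), x, 2 * x + 1, ("dry",) * 5)
        fit = regress(p)
        assert fit.slope == pytest.approx(2.0, rel=1e-12)
        assert fit.intercept == pytest.approx(1.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.p_value < 1e-10

    def test_r_squared_equals_squared_pearson(self, rng):
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        p = PairedTraitSet("a", tuple(map(str, range(40))), x, y, ("dry",) * 40)
        fit = regress(p)
        assert fit.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, rel=1e-12)

    def test_independent_data_f_near_one(self, rng):
        """Under the null, F averages ~df2/(df2-2) ~ 1 and R² ~ 1/(n-1)."""
        n = 2000
        x, y = rng.normal(size=n), rng.normal(size=n)
        p = PairedTraitSet("a", tuple(map(str, range(n))), x, y, ("dry",) * n)
        fit = regress(p)
        assert fit.r_squared < 0.01
        assert fit.f_statistic < 5.0

    def test_order_invariance(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        p1 = PairedTraitSet("a", tuple(map(str, range(10))), x, y, ("dry",) * 10)
        perm = rng.permutation(10)
        p2 = PairedTraitSet("a", tuple(map(str, perm)), x[perm], y[perm], ("dry",) * 10)
        f1, f2 = regress(p1), regress(p2)
        assert f1.slope == pytest.approx(f2.slope, rel=1e-12)
        assert f1.r_squared == pytest.approx(f2.r_squared, rel=1e-12)

    def test_zero_variance_degenerate(self):
        p = PairedTraitSet("a", tuple("abcd"), np.ones(4), np.arange(4.0), ("dry",) * 4)
        with pytest.raises(DegenerateError):
            regress(p)


class TestTreeCovariance:
    def test_three_tip_hand_tree(self):
        import dendropy

        tree = dendropy.Tree.get(data="((A:1,B:1):2,C:3);", schema="newick")
        cov, labels = tree_covariance(tree)
        assert labels == ["A", "B", "C"]
        expect = np.array([[3.0, 2.0, 0.0], [2.0, 3.0, 0.0], [0.0, 0.0, 3.0]])
        np.testing.assert_allclose(cov, expect, atol=1e-7)

    def test_polytomy_resolved_and_floored(self):
        import dendropy

        tree = dendropy.Tree.get(data="(A:1,B:1,C:1,D:1);", schema="newick")
        cov, _ = tree_covariance(tree, min_branch_length=1e-8)
        # positive definite after flooring
        assert np.all(np.linalg.eigvalsh(cov) > 0)


class TestBlombergK:
    def test_brownian_traits_give_k_near_one(self):
        ks = []
        for s in range(60):
            tree = gen_tree(64, seed=1000 + s)
            traits = gen_bm_traits(tree, sigma2=1.0, seed=2000 + s)
            ks.append(blomberg_k(tree, traits, n_perm=1, seed=s).k)
        assert np.mean(ks) == pytest.approx(1.0, abs=0.15)

    def test_strong_signal_detected_weak_for_shuffled(self):
        rng = np.random.default_rng(7)
        small_ps, shuffled_ps = [], []
        for s in range(20):
            tree = gen_tree(32, seed=300 + s)
            traits = gen_bm_traits(tree, sigma2=1.0, seed=400 + s)
            small_ps.append(blomberg_k(tree, traits, n_perm=199, seed=s).p_value)
            labels = list(traits)
            vals = rng.permutation([traits[l] for l in labels])
            shuffled = dict(zip(labels, vals))
            shuffled_ps.append(blomberg_k(tree, shuffled, n_perm=199, seed=s).p_value)
        assert np.mean(np.array(small_ps) < 0.05) > np.mean(np.array(shuffled_ps) < 0.05)

    def test_constant_trait_degenerate(self):
        tree = gen_tree(8, seed=1)
        with pytest.raises(DegenerateError):
            blomberg_k(tree, {l: 1.0 for l in (t.label for t in tree.taxon_namespace)})

    def test_too_few_matched_tips(self):
        tree = gen_tree(8, seed=1)
        labels = [t.label for t in tree.taxon_namespace]
        with pytest.raises(InsufficientDataError):
            blomberg_k(tree, {labels[0]: 1.0, labels[1]: 2.0, "nope": 3.0})

    def test_unmatched_reported_analysis_on_intersection(self):
        tree = gen_tree(10, seed=5)
        traits = gen_bm_traits(tree, 1.0, seed=6)
        traits["Unknown species"] = 0.5
        tip = sorted(l for l in traits if l.startswith("sp"))[0]
        del traits[tip]
        res = blomberg_k(tree, traits, n_perm=19, seed=0)
        assert res.n_tips == 9
        assert "Unknown species" in res.unmatched_traits
        assert len(res.unmatched_tips) == 1

    def test_same_seed_reproducible_and_tip_order_invariant(self):
        tree = gen_tree(12, seed=9)
        traits = gen_bm_traits(tree, 1.0, seed=10)
        r1 = blomberg_k(tree, traits, n_perm=99, seed=3)
        reordered = {k: traits[k] for k in reversed(sorted(traits))}
        r2 = blomberg_k(tree, reordered, n_perm=99, seed=3)
        assert r1.k == pytest.approx(r2.k, rel=1e-14)
        assert r1.p_value == r2.p_value

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="R not available for the independent oracle")
    def test_matches_picante_oracle(self, tmp_path):
        """Independent cross-check of K against the R picante implementation."""
        tree = gen_tree(16, seed=3)
        traits = gen_bm_traits(tree, sigma2=1.0, seed=5)
        ours = blomberg_k(tree, traits, n_perm=1, seed=0).k
        tree.write(path=str(tmp_path / "t.nwk"), schema="newick")
        with open(tmp_path / "x.csv", "w") as fh:
            fh.write("species,value\n")
            for k in sorted(traits):
                fh.write(f"{k},{traits[k]!r}\n")
        out = subprocess.run(
            ["Rscript", "-e",
             'suppressMessages(library(picante));'
             f'phy <- read.tree("{tmp_path}/t.nwk");'
             f'x <- read.csv("{tmp_path}/x.csv");'
             'v <- setNames(x$value, x$species);'
             'cat(sprintf("%.12f", Kcalc(v[phy$tip.label], phy)))'],
            capture_output=True, text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        assert ours == pytest.approx(float(out.stdout.strip()), rel=1e-8)


class TestEquivalenceFit:
    def test_noiseless_recovery(self):
        true = UptakeKinetics(v_max=0.5, k_m=50.0)
        fit = equivalence_fit(30, true, noise=0.0, seed=1)
        assert fit.converged
        mm = fit.mm.as_kinetics()
        assert mm.v_max == pytest.approx(true.v_max, rel=1e-6)
        assert mm.k_m == pytest.approx(true.k_m, rel=1e-6)
        ho = fit.holling.as_traits()
        assert ho.a == pytest.approx(true.v_max / true.k_m, rel=1e-6)
        assert ho.h == pytest.approx(1 / true.v_max, rel=1e-6)

    def test_noisy_fits_share_their_optimum(self):
        true = UptakeKinetics(v_max=0.5, k_m=50.0)
        for seed in range(5):
            fit = equivalence_fit(40, true, noise=0.05, seed=seed)
            assert fit.converged
            assert fit.rss_rel_diff < 1e-8
            assert fit.translation_rel_err < 1e-6
            assert fit.max_curve_rel_diff() < 1e-6

    def test_model_results_surface(self):
        true = UptakeKinetics(v_max=1.0, k_m=10.0)
        fit = equivalence_fit(25, true, noise=0.02, seed=3)
        res = fit.mm
        assert res.bse.shape == (2,)
        assert np.all(res.bse > 0)
        assert "v_max" in res.summary() and "RSS" in res.summary()
        preds = res.predict(np.array([10.0]))
        assert preds[0] == pytest.approx(true.v_max / 2, rel=0.2)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            equivalence_fit(3, UptakeKinetics(1.0, 1.0))

    def test_model_rejects_bad_inputs(self):
        with pytest.raises(Exception):
            UptakeCurveModel(np.ones(5), np.ones(4))
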