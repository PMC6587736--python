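import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare

from melanomorph import synthetic
from melanomorph.io_core import is_ultrametric, tree_depth, vcv_matrix
from melanomorph.synthetic import (
    SimulationConfig,
    TypeRegime,
    apply_shrinkage,
    sample_melanosomes,
    simulate_species_traits,
    simulate_tree,
)

from conftest import small_regimes


def naive_yule_lineages_at_half_time(rate: float, n_tips: int, rng) -> int:
    """Independent event-by-event pure-birth oracle: number of lineages alive
    at half of the total simulation time."""
    times = [0.0, 0.0]  # birth time per lineage; start with 2
    t = 0.0
    events = []
    k = 2
    while k < n_tips:
        t += rng.exponential(1.0 / (rate * k))
        events.append(t)
        k += 1
    t_end = t + rng.exponential(1.0 / (rate * k))
    half = t_end / 2.0
    return 2 + sum(1 for e in events if e <= half)


def lineages_at_relative_depth(tree, frac: float) -> int:
    from melanomorph.io_core import _node_depths

    depths = _node_depths(tree)
    target = frac * tree_depth(tree)
    count = 0
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        if depths[parent] <= target < depths[node]:
            count += 1
    return count


class TestSimulateTree:
    def test_two_species_cherry(self):
        tree = simulate_tree(SimulationConfig(n_species=2, seed=0))
        tips = tree.leaf_nodes()
        assert len(tips) == 2
        assert tips[0].edge.length == pytest.approx(tips[1].edge.length)

    def test_rejects_single_species(self):
        with pytest.raises(ValueError):
            simulate_tree(SimulationConfig(n_species=1, seed=0))

    def test_deterministic_newick(self):
        a = simulate_tree(SimulationConfig(n_species=20, seed=9))
        b = simulate_tree(SimulationConfig(n_species=20, seed=9))
        assert a.as_string(schema="newick") == b.as_string(schema="newick")

    def test_ultrametric_depth_one(self):
        tree = simulate_tree(SimulationConfig(n_species=33, seed=4))
        assert is_ultrametric(tree)
        assert tree_depth(tree) == pytest.approx(1.0)

    def test_lineage_count_matches_bruteforce_oracle(self):
        """Mean lineage count at half depth agrees with an independent
        event-by-event pure-birth simulation (500 replicates each)."""
        rng = np.random.default_rng(77)
        oracle = np.mean(
            [naive_yule_lineages_at_half_time(1.0, 64, rng) for _ in range(500)]
        )
        cfg = [
            lineages_at_relative_depth(
                simulate_tree(SimulationConfig(n_species=64, seed=10_000 + s)), 0.5
            )
            for s in range(500)
        ]
        ours = np.mean(cfg)
        assert ours == pytest.approx(oracle, rel=0.10)


class TestSpeciesTraits:
    def test_zero_rate_gamma_zero_all_at_root(self):
        cfg = SimulationConfig(
            n_species=16, seed=3, bm_rate=0.0, gamma=0.0, type_regimes=[]
        )
        tree = simulate_tree(cfg)
        traits = simulate_species_traits(tree, cfg)
        assert traits["true_mean_log_length"].nunique() == 1
        assert traits["true_mean_log_length"].iloc[0] == pytest.approx(math.log(0.9))

    def test_gamma_one_painted_at_optimum(self):
        regimes = [TypeRegime("hollow_flat", 2, 2.5, 0.9, True, True)]
        cfg = SimulationConfig(
            n_species=32, seed=8, gamma=1.0, type_regimes=regimes
        )
        tree = simulate_tree(cfg)
        traits = simulate_species_traits(tree, cfg)
        painted = traits[traits["melanosome_type"] == "hollow_flat"]
        assert len(painted) >= 2
        np.testing.assert_allclose(
            painted["true_mean_log_length"], math.log(2.5), atol=1e-12
        )

    def test_bm_tip_covariance_matches_closed_form(self, tree32):
        """Tip covariance across 1000 replicates ~ rate x shared-path matrix."""
        rate = 0.1
        tips = [leaf.taxon.label for leaf in tree32.leaf_node_iter()]
        C = vcv_matrix(tree32, tips)
        rng = np.random.default_rng(99)
        draws = []
        for _ in range(1000):
            tip_vals = synthetic._brownian_tips(tree32, rate, 0.0, rng)
            draws.append([tip_vals[sp] for sp in tips])
        draws = np.array(draws)
        emp = np.cov(draws, rowvar=False)
        np.testing.assert_allclose(emp, rate * C, atol=0.025)

    def test_impossible_origins_raise(self):
        regimes = [TypeRegime("solid_flat", 40, 1.2, 0.45, True, False)]
        cfg = SimulationConfig(n_species=16, seed=1, type_regimes=regimes)
        tree = simulate_tree(cfg)
        with pytest.raises(Exception, match="origins|clades"):
            simulate_species_traits(tree, cfg)

    def test_composition_matches_proportions(self):
        """Pooled category counts over 200 replicates pass a chi-square test
        against the configured proportions at alpha = 0.01."""
        counts = {c: 0 for c in ("black", "brown", "grey", "iridescent")}
        props = None
        for s in range(200):
            cfg = SimulationConfig(seed=20_000 + s)
            props = cfg.category_proportions
            tree = simulate_tree(cfg)
            traits = simulate_species_traits(tree, cfg)
            for c, k in traits["color_category"].value_counts().items():
                counts[str(c)] += int(k)
        total = sum(counts.values())
        obs = [counts[c] for c in props]
        exp = [props[c] * total for c in props]
        assert chisquare(obs, exp).pvalue > 0.01


class TestSampleMelanosomes:
    def _one_species(self, log_len=0.0, log_wid=math.log(0.4)):
        return pd.DataFrame(
            [
                dict(
                    species="A_a",
                    color_category="black",
                    melanosome_type="",
                    origin=-1,
                    flatness=False,
                    hollowness=False,
                    true_mean_log_length=log_len,
                    true_mean_log_width=log_wid,
                )
            ]
        )

    def test_degenerate_cv_all_identical(self):
        cfg = SimulationConfig(seed=0, within_species_cv=1e-9,
                               melanosomes_per_sample=10)
        table = sample_melanosomes(self._one_species(), cfg)
        assert table["length_um"].std() == pytest.approx(0.0, abs=1e-8)

    def test_sample_cv_near_nominal(self):
        cfg = SimulationConfig(seed=2, within_species_cv=0.2,
                               melanosomes_per_sample=2000)
        table = sample_melanosomes(self._one_species(), cfg)
        L = table["length_um"]
        assert L.mean() == pytest.approx(1.0, abs=0.03)
        assert L.std(ddof=1) / L.mean() == pytest.approx(0.2, abs=0.02)

    def test_hollow_flat_regime_reaches_large_sizes(self):
        """A 2.5-um hollow-flat optimum yields sample means near 2.5 um."""
        regimes = [TypeRegime("hollow_flat", 2, 2.5, 0.9, True, True)]
        cfg = SimulationConfig(
            n_species=32, seed=6, gamma=1.0, type_regimes=regimes,
            melanosomes_per_sample=200,
        )
        tree = simulate_tree(cfg)
        traits = simulate_species_traits(tree, cfg)
        table = sample_melanosomes(traits, cfg)
        hf = table[table["melanosome_type"] == "hollow_flat"]
        means = hf.groupby("sample_id")["length_um"].mean()
        np.testing.assert_allclose(means, 2.5, rtol=0.08)

    def test_width_never_exceeds_length(self, default_dataset):
        _, _, _, table = default_dataset
        assert (table["width_um"] <= table["length_um"]).all()

    def test_deterministic(self):
        cfg = SimulationConfig(n_species=16, seed=11, type_regimes=[])
        a = synthetic.make_dataset(cfg)[2]
        b = synthetic.make_dataset(cfg)[2]
        pd.testing.assert_frame_equal(a, b)


class TestShrinkage:
    def test_identity_at_zero(self, default_dataset):
        _, _, _, table = default_dataset
        pd.testing.assert_frame_equal(apply_shrinkage(table, 0.0), table)

    def test_thirty_percent(self):
        table = pd.DataFrame(
            dict(sample_id=["s"], species=["A"], color_category=["black"],
                 melanosome_type=[""], length_um=[1.0], width_um=[0.5])
        )
        out = apply_shrinkage(table, 0.3)
        assert out["length_um"].iloc[0] == pytest.approx(0.7)
        assert out["width_um"].iloc[0] == pytest.approx(0.35)

    @pytest.mark.parametrize("fraction", [0.1, 0.2, 0.3, 0.85])
    def test_aspect_ratio_invariant(self, fraction, default_dataset):
        _, _, _, table = default_dataset
        out = apply_shrinkage(table, fraction)
        np.testing.assert_allclose(
            out["length_um"] / out["width_um"],
            table["length_um"] / table["width_um"],
        )

    def test_rejects_bad_fraction(self, default_dataset):
        _, _, _, table = default_dataset
        with pytest.raises(ValueError):
            apply_shrinkage(table, 1.0)
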