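"""Unit and property tests of the latent-trait Likert response simulator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtr

from likertfa.items import ItemDefinition, load_item_pool
from likertfa.simulate import (
    DISTRIBUTIONS,
    ERROR_MODELS,
    DistributionSpec,
    SimulationCondition,
    build_grid,
    generate_dataset,
    generate_responses,
    perturb,
    sample_latent,
    true_score,
)

LARGE = ERROR_MODELS["large"]
SMALL = ERROR_MODELS["small"]


class TestItemPool:
    def test_pool_matches_published_boundaries(self, pool):
        assert len(pool) == 27
        assert pool[0].boundaries == (13, 21, 29, 36)
        assert pool[11].boundaries == (48, 57, 66, 76)
        assert pool[26].boundaries == (21, 38, 51, 59)
        for item in pool:
            assert np.all(np.diff(item.boundaries) > 0)

    def test_invalid_boundaries_rejected(self):
        with pytest.raises(ValueError):
            ItemDefinition(1, (10, 9, 11, 12))


class TestLatentSampling:
    def test_normal_moments(self):
        x = sample_latent(DISTRIBUTIONS["normal"], 100_000, seed=1).positions
        assert x.mean() == pytest.approx(50, abs=0.3)
        assert x.std() == pytest.approx(20, abs=0.3)

    def test_uniform_support(self):
        x = sample_latent(DISTRIBUTIONS["uniform"], 1000, seed=2).positions
        assert np.all((x >= 0) & (x <= 100))

    def test_skew_normal_skewness(self):
        # closed form for shape alpha=5: delta = 5/sqrt(26),
        # g1 = (4-pi)/2 * (delta*sqrt(2/pi))^3 / (1 - 2 delta^2/pi)^1.5
        delta = 5 / np.sqrt(26)
        mu = delta * np.sqrt(2 / np.pi)
        g1 = (4 - np.pi) / 2 * mu**3 / (1 - mu**2) ** 1.5
        assert g1 == pytest.approx(0.851, abs=5e-4)
        x = sample_latent(DISTRIBUTIONS["skew_normal"], 1_000_000, seed=3).positions
        from scipy.stats import skew

        assert skew(x) == pytest.approx(g1, abs=0.01)

    def test_bimodal_mixture(self):
        x = sample_latent(DISTRIBUTIONS["bimodal"], 100_000, seed=4).positions
        # Bernoulli(0.5) membership: about half below the midpoint
        assert np.mean(x < 50) == pytest.approx(0.5, abs=0.01)
        assert x.mean() == pytest.approx(50, abs=0.3)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            DistributionSpec("lognormal", {})


class TestTrueScore:
    def test_published_worked_examples(self, pool):
        assert true_score(33, pool[0]) == 4  # item 1
        assert true_score(33, pool[11]) == 1  # item 12

    def test_boundary_convention(self, pool):
        item = pool[0]  # boundaries 13/21/29/36
        assert true_score(12.999, item) == 1
        assert true_score(13.0, item) == 2  # category k+1 includes boundary k
        assert true_score(36.0, item) == 5
        assert true_score(100.0, item) == 5

    def test_monotone_in_position(self, pool):
        grid = np.linspace(-20, 120, 2001)
        for item in pool:
            scores = true_score(grid, item)
            assert np.all(np.diff(scores) >= 0)


class TestPerturb:
    @pytest.mark.parametrize(
        "cat, z, error, expected",
        [
            (3, 0.5, LARGE, 3),  # |z| <= 1: no deviation
            (3, 1.5, LARGE, 4),  # 1 < |z| <= 2: one category up
            (3, -2.5, LARGE, 1),  # 2 < |z| <= 3: two categories down
            (3, 3.5, LARGE, 5),  # |z| > 3 shifts 3, clamped from 6
            (5, 2.5, LARGE, 5),  # truncation at the top of the scale
            (3, 1.1, SMALL, 3),  # small-error cutoffs are 1.2/2.2/3
            (3, 1.3, SMALL, 4),
        ],
    )
    def test_discretisation_rule(self, cat, z, error, expected):
        assert perturb(cat, z, error) == expected

    @given(
        cat=st.integers(min_value=1, max_value=5),
        z=st.floats(min_value=-6, max_value=6, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_symmetric_before_clamping(self, cat, z):
        raw = int(np.searchsorted(np.asarray(LARGE.cutoffs), abs(z), side="left"))
        up = perturb(cat, z, LARGE) - cat
        down = perturb(cat, -z, LARGE) - cat
        # shifts are mirror images whenever clamping cannot interfere
        if 1 <= cat - raw and cat + raw <= 5:
            assert up == -down

    @pytest.mark.parametrize(
        "error, expected_rate",
        [(LARGE, 2 * (1 - ndtr(1.0))), (SMALL, 2 * (1 - ndtr(1.2)))],
    )
    def test_perturbation_rate(self, error, expected_rate):
        # 'slightly less than one out of three' (large) / 'one out of four' (small)
        rng = np.random.default_rng(5)
        z = rng.standard_normal(200_000)
        rate = np.mean(perturb(np.full(z.shape, 3), z, error) != 3)
        # category 3 never clamps for shifts 1-2; shift 3 clamps, still counted as change
        assert rate == pytest.approx(expected_rate, abs=0.005)


class TestDatasetGeneration:
    def _condition(self, seed=9, n_items=5, n=500):
        return SimulationCondition(
            distribution=DISTRIBUTIONS["normal"],
            n_items=n_items,
            error=LARGE,
            replicate=0,
            seed=seed,
            n_respondents=n,
            distribution_name="normal",
        )

    def test_shape_and_range(self, pool):
        R = generate_dataset(self._condition(), pool)
        assert R.responses.shape == (500, 5)
        assert R.responses.min() >= 1 and R.responses.max() <= 5
        assert len(set(R.item_ids)) == 5

    def test_bitwise_determinism(self, pool):
        R1 = generate_dataset(self._condition(), pool)
        R2 = generate_dataset(self._condition(), pool)
        assert np.array_equal(R1.responses, R2.responses)
        assert R1.item_ids == R2.item_ids

    def test_error_leaves_latent_sample_untouched(self, pool):
        # regenerating responses from a fixed latent sample only moves responses
        from likertfa.simulate import sample_latent

        latent = sample_latent(DISTRIBUTIONS["normal"], 500, seed=11)
        before = latent.positions.copy()
        rng = np.random.default_rng(12)
        r1 = generate_responses(latent, pool[:5], LARGE, rng)
        r2 = generate_responses(latent, pool[:5], LARGE, rng)
        assert np.array_equal(latent.positions, before)
        assert not np.array_equal(r1, r2)

    def test_too_many_items_rejected(self, pool):
        with pytest.raises(ValueError):
            generate_dataset(self._condition(n_items=28), pool)

    def test_skewed_population_concentrates_low_categories(self, pool):
        # item 7 under the skew-normal population: mass piles into category 1
        cond = SimulationCondition(
            distribution=DISTRIBUTIONS["skew_normal"],
            n_items=27,
            error=LARGE,
            replicate=0,
            seed=13,
            n_respondents=2000,
            distribution_name="skew_normal",
        )
        R = generate_dataset(cond, pool)
        col = R.responses[:, R.item_ids.index(7)]
        freqs = np.bincount(col, minlength=6)[1:]
        assert freqs[0] == freqs.max()
        assert np.all(np.diff(freqs) <= 0)  # monotone decreasing across categories


class TestGrid:
    def test_default_grid_size(self):
        conds = build_grid(master_seed=1, replicates=100)
        assert len(conds) == 2400
        assert sum(c.n_items == 5 for c in conds) == 800

    def test_single_replicate_grid(self):
        assert len(build_grid(master_seed=1, replicates=1)) == 24

    def test_seed_determinism(self):
        a = build_grid(master_seed=3, replicates=2)
        b = build_grid(master_seed=3, replicates=2)
        assert [c.seed for c in a] == [c.seed for c in b]
        c = build_grid(master_seed=4, replicates=2)
        assert [x.seed for x in a] != [x.seed for x in c]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            build_grid(master_seed=1, replicates=1, n_items=[])
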