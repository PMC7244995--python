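"""Weighted-kappa agreement statistics against brute-force and analytic oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from privvae.agreement import (
    NOT_RATABLE,
    KappaUndefinedError,
    RatingTable,
    interpret_kappa,
    interrater_agreement,
    intrarater_agreement,
    mean_rating_difference,
    ratable_proportion,
    weighted_kappa,
)
from privvae.synthetic import RaterModel, simulate_ratings

from oracles import analytic_rater_kappa, kappa_loop


def _table(columns, condition="original"):
    ids = [f"v{i}" for i in range(len(next(iter(columns.values()))))]
    return RatingTable.from_columns(columns, ids, condition=condition)


class TestWeightedKappa:
    def test_perfect_agreement_is_one(self, rng):
        a = rng.integers(0, 5, 40)
        res = weighted_kappa(a, a.copy())
        assert res.kappa == pytest.approx(1.0)
        assert res.n_pairs_used == 40
        assert res.interpretation == "almost perfect"

    def test_exact_independence_table_gives_zero(self):
        """Cells = outer product of the marginals => chance agreement."""
        marginals = np.array([10, 20, 40, 20, 10])
        n = marginals.sum()
        a, b = [], []
        for i in range(5):
            for j in range(5):
                count = marginals[i] * marginals[j] // n
                a.extend([i] * count)
                b.extend([j] * count)
        res = weighted_kappa(a, b)
        assert res.kappa == pytest.approx(0.0, abs=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(0, 2**31 - 1), st.sampled_from(["linear", "quadratic"]))
    def test_matches_brute_force_oracle(self, seed, scheme):
        r = np.random.default_rng(seed)
        a = r.integers(0, 5, 50)
        b = np.clip(a + r.integers(-2, 3, 50), 0, 4)
        expected = kappa_loop(a, b, scheme)
        if np.isnan(expected):
            with pytest.raises(KappaUndefinedError):
                weighted_kappa(a, b, weights=scheme)
        else:
            res = weighted_kappa(a, b, weights=scheme)
            assert res.kappa == pytest.approx(expected, abs=1e-12)
            assert -1.0 <= res.kappa <= 1.0

    def test_nr_pairs_excluded_and_counted(self):
        a = [2, 3, NOT_RATABLE, 1, 0]
        b = [1, 3, 2, NOT_RATABLE, 0]
        res = weighted_kappa(a, b)
        assert res.n_pairs_used == 3
        assert res.kappa == pytest.approx(kappa_loop([2, 3, 0], [1, 3, 0]), abs=1e-12)

    def test_fewer_than_two_usable_pairs_rejected(self):
        with pytest.raises(ValueError, match="usable rating pairs"):
            weighted_kappa([1, NOT_RATABLE], [1, 2])

    def test_single_identical_category_is_undefined_not_zero(self):
        with pytest.raises(KappaUndefinedError, match="undefined"):
            weighted_kappa([2, 2, 2], [2, 2, 2])

    def test_constant_but_different_categories_is_defined(self):
        # marginals have no overlap: observed disagreement equals chance
        res = weighted_kappa([1, 1, 1], [3, 3, 3])
        assert res.kappa == pytest.approx(0.0, abs=1e-12)

    def test_invalid_ratings_rejected(self):
        with pytest.raises(ValueError, match="rating must be"):
            weighted_kappa([1, 7], [1, 2])


class TestPermutationInvariance:
    def test_video_order_does_not_matter(self, rng):
        n = 30
        cols = {
            "r1": list(rng.integers(0, 5, n)),
            "r2": list(rng.integers(0, 5, n)),
            "r3": list(rng.integers(0, 5, n)),
        }
        table = _table(cols)
        perm = rng.permutation(n)
        shuffled = RatingTable(table.data.iloc[perm], condition=table.condition)
        a = interrater_agreement(table)
        b = interrater_agreement(shuffled)
        assert a.mean_kappa == pytest.approx(b.mean_kappa, abs=1e-12)


class TestIntrarater:
    def test_identical_tables_give_unity_everywhere(self, rng):
        cols = {f"r{i}": list(rng.integers(0, 5, 20)) for i in range(4)}
        orig = _table(cols, "original")
        dec = _table(cols, "decoded")
        res = intrarater_agreement(orig, dec)
        assert res.pooled.kappa == pytest.approx(1.0)
        assert all(k.kappa == pytest.approx(1.0) for k in res.per_rater.values())
        assert not res.excluded

    def test_pooled_kappa_decreases_with_decoded_noise(self):
        """More miscoding noise on the decoded condition => lower agreement."""
        grades = list(np.random.default_rng(0).integers(0, 5, 100))
        raters = [RaterModel(seed=s) for s in range(3)]
        orig = simulate_ratings(grades, raters, condition="original")
        pooled = []
        for sd in (0.0, 0.8, 2.0):
            noisy = [RaterModel(miscode_sd=sd, seed=100 + s) for s in range(3)]
            dec = simulate_ratings(grades, noisy, condition="decoded")
            pooled.append(intrarater_agreement(orig, dec).pooled.kappa)
        assert pooled[0] == pytest.approx(1.0)
        assert pooled[0] > pooled[1] > pooled[2]

    def test_all_nr_rater_excluded_with_flag_others_unaffected(self, rng):
        cols = {"r1": list(rng.integers(0, 5, 10)), "r2": list(rng.integers(0, 5, 10))}
        orig = _table(cols, "original")
        dec_cols = {"r1": [NOT_RATABLE] * 10, "r2": cols["r2"]}
        dec = _table(dec_cols, "decoded")
        res = intrarater_agreement(orig, dec)
        assert "r1" in res.excluded and "usable" in res.excluded["r1"]
        assert res.per_rater["r2"].kappa == pytest.approx(1.0)

    def test_misaligned_identifiers_listed(self, rng):
        orig = _table({"r1": [1, 2, 3]})
        dec = RatingTable.from_columns({"r2": [1.0, 2, 3]}, ["v0", "v1", "vX"],
                                       condition="decoded")
        with pytest.raises(ValueError, match="misaligned"):
            intrarater_agreement(orig, dec)


class TestInterrater:
    def test_identical_raters_agree_perfectly(self, rng):
        col = list(rng.integers(0, 5, 25))
        res = interrater_agreement(_table({"r1": col, "r2": col, "r3": col}))
        assert res.mean_kappa == pytest.approx(1.0)

    def test_two_raters_mean_equals_single_pairwise_kappa(self, rng):
        a = list(rng.integers(0, 5, 30))
        b = list(np.clip(np.asarray(a) + rng.integers(-1, 2, 30), 0, 4))
        res = interrater_agreement(_table({"r1": a, "r2": b}))
        assert res.mean_kappa == pytest.approx(weighted_kappa(a, b).kappa, abs=1e-12)

    def test_noisier_raters_agree_less(self):
        grades = list(np.random.default_rng(1).integers(0, 5, 200))
        low = simulate_ratings(grades, [RaterModel(miscode_sd=0.3, seed=s)
                                        for s in range(4)])
        high = simulate_ratings(grades, [RaterModel(miscode_sd=1.5, seed=s)
                                         for s in range(4)])
        assert (interrater_agreement(low).mean_kappa
                > interrater_agreement(high).mean_kappa)

    def test_pairs_without_shared_videos_flagged_and_skipped(self, rng):
        n = 10
        cols = {
            "r1": list(rng.integers(0, 5, n)),
            "r2": [NOT_RATABLE] * n,
            "r3": list(rng.integers(0, 5, n)),
        }
        res = interrater_agreement(_table(cols))
        assert ("r1", "r2") in res.excluded_pairs
        assert np.isfinite(res.mean_kappa)

    def test_single_rater_rejected(self, rng):
        with pytest.raises(ValueError, match=">= 2 raters"):
            interrater_agreement(_table({"r1": [1, 2, 3]}))


class TestSimulatedRaterRecovery:
    def test_estimated_kappa_matches_analytic_confusion_matrix(self):
        """Two simulated raters vs the kappa implied by their exact cell
        probabilities: agreement within 0.05 at 500 videos."""
        grades = [g for g in range(5) for _ in range(100)]
        truth = RaterModel(miscode_sd=0.0, seed=11)
        noisy = RaterModel(miscode_sd=0.7, seed=22)
        table = simulate_ratings(grades, [truth, noisy])
        est = weighted_kappa(table.column("rater00"), table.column("rater01"))
        exact = analytic_rater_kappa(truth, noisy, grade_probs=[0.2] * 5)
        assert est.kappa == pytest.approx(exact, abs=0.05)


class TestSummaries:
    def test_mean_difference_identity_and_shift(self, rng):
        cols = {f"r{i}": list(rng.integers(0, 4, 15)) for i in range(3)}
        orig = _table(cols, "original")
        assert mean_rating_difference(orig, _table(cols, "decoded")) == 0.0
        plus1 = {k: [min(v + 1, 4) for v in vals] for k, vals in cols.items()}
        orig1 = _table(plus1, "original")
        assert mean_rating_difference(orig1, _table(cols, "decoded")) == pytest.approx(
            np.mean([min(v + 1, 4) - v for vals in cols.values() for v in vals])
        )

    def test_mean_difference_excludes_nr_pairs(self):
        orig = _table({"r": [2, 3, NOT_RATABLE, 1]}, "original")
        dec = _table({"r": [1, 3, 2, 1]}, "decoded")
        assert mean_rating_difference(orig, dec) == pytest.approx(1 / 3)

    def test_no_shared_ratable_pairs_rejected(self):
        orig = _table({"r": [NOT_RATABLE, 1]}, "original")
        dec = _table({"r": [1, NOT_RATABLE]}, "decoded")
        with pytest.raises(ValueError, match="ratable in both"):
            mean_rating_difference(orig, dec)

    def test_ratable_proportion_counts_non_nr_cells(self, rng):
        """172 ratable cells of 200 gives 0.86."""
        vals = [int(v) for v in rng.integers(0, 5, 172)] + [NOT_RATABLE] * 28
        rng.shuffle(vals)
        cols = {f"r{i}": vals[i * 20 : (i + 1) * 20] for i in range(10)}
        assert ratable_proportion(_table(cols)) == pytest.approx(0.86)


class TestInterpretation:
    @pytest.mark.parametrize(
        "kappa,label",
        [
            (-0.5, "chance or worse"),
            (0.0, "chance or worse"),
            (0.1, "slight"),
            (0.2, "slight"),
            (0.317, "fair"),
            (0.4, "fair"),
            (0.459, "moderate"),
            (0.6, "moderate"),
            (0.302, "fair"),
            (0.75, "substantial"),
            (0.95, "almost perfect"),
            (1.0, "almost perfect"),
        ],
    )
    def test_band_mapping(self, kappa, label):
        assert interpret_kappa(kappa) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[-1, 1\]"):
            interpret_kappa(1.5)
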