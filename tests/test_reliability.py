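"""Agreement statistics checked against independent brute-force arithmetic.

The oracles here recompute Fleiss' kappa from explicit pair-counting over
subjects and Krippendorff's alpha from an explicitly assembled coincidence
matrix, using plain Python loops over label strings — sharing no code with
the implementation under test.
"""
import numpy as np
import pandas as pd
import pytest

from conftest import random_ratings
from epiqc import reliability as rel
from epiqc.errors import InsufficientDataError, UndefinedStatisticError
from epiqc.types import LABELS, RatingsTable


# ---------------------------------------------------------------------------
# Brute-force oracles

def fleiss_oracle(frame: pd.DataFrame) -> float:
    """Fleiss kappa by explicit agreeing-pair counting on complete cases."""
    rows = [list(r) for _, r in frame.iterrows() if not any(pd.isna(v) for v in r)]
    n_raters = len(frame.columns)
    agree = []
    for row in rows:
        pairs = agreeing = 0
        for a in range(n_raters):
            for b in range(n_raters):
                if a != b:
                    pairs += 1
                    agreeing += row[a] == row[b]
        agree.append(agreeing / pairs)
    p_o = sum(agree) / len(agree)
    all_labels = [lab for row in rows for lab in row]
    p_e = sum((all_labels.count(c) / len(all_labels)) ** 2 for c in LABELS)
    return (p_o - p_e) / (1 - p_e)


def categorywise_oracle(frame: pd.DataFrame, category: str) -> float:
    """Fleiss per-category kappa from its defining proportions, by loops."""
    rows = [list(r) for _, r in frame.iterrows() if not any(pd.isna(v) for v in r)]
    ns, nr = len(rows), len(frame.columns)
    counts = [sum(v == category for v in row) for row in rows]
    pj = sum(counts) / (ns * nr)
    pjk = (sum(c * c for c in counts) - ns * nr * pj) / (ns * nr * (nr - 1) * pj)
    return (pjk - pj) / (1 - pj)


def alpha_oracle(frame: pd.DataFrame) -> float:
    """Krippendorff alpha via an explicitly built coincidence matrix."""
    coincidence = {(a, b): 0.0 for a in LABELS for b in LABELS}
    for _, row in frame.iterrows():
        vals = [v for v in row if isinstance(v, str)]
        if len(vals) < 2:
            continue
        for i, a in enumerate(vals):
            for j, b in enumerate(vals):
                if i != j:
                    coincidence[(a, b)] += 1.0 / (len(vals) - 1)
    n = sum(coincidence.values())
    n_c = {c: sum(coincidence[(c, k)] for k in LABELS) for c in LABELS}
    d_o = sum(coincidence[(a, b)] for a in LABELS for b in LABELS if a != b)
    d_e = sum(n_c[a] * n_c[b] for a in LABELS for b in LABELS if a != b) / (n - 1)
    if d_e == 0:
        return 1.0
    return 1 - d_o / d_e


# ---------------------------------------------------------------------------
# Fleiss kappa

class TestFleissKappa:
    def test_perfect_agreement(self, rng):
        labels = rng.choice(LABELS, size=20)
        frame = pd.DataFrame({"a": labels, "b": labels}, index=[f"s{i}" for i in range(20)])
        res = rel.fleiss_kappa(RatingsTable(frame.astype(object)))
        assert res.kappa == pytest.approx(1.0)
        assert res.n_subjects_used == 20

    def test_chance_agreement_near_zero(self):
        table = random_ratings(np.random.default_rng(11), 10_000, 2)
        res = rel.fleiss_kappa(table)
        se = res.kappa / res.z if res.z != 0 else 1.0
        assert abs(res.kappa) < 3 * abs(se)

    def test_fixed_toy_table_matches_oracle(self):
        rows = [
            ("include", "include"), ("include", "uncertain"), ("exclude", "exclude"),
            ("uncertain", "uncertain"), ("include", "include"), ("exclude", "include"),
            ("exclude", "exclude"), ("include", "include"), ("uncertain", "exclude"),
            ("include", "include"),
        ]
        frame = pd.DataFrame(rows, columns=["a", "b"], index=[f"s{i}" for i in range(10)])
        res = rel.fleiss_kappa(RatingsTable(frame.astype(object)))
        assert res.kappa == pytest.approx(fleiss_oracle(frame), abs=1e-12)

    def test_matches_statsmodels_on_random_tables(self, rng):
        from statsmodels.stats.inter_rater import aggregate_raters, fleiss_kappa

        for _ in range(20):
            table = random_ratings(rng, int(rng.integers(5, 15)), int(rng.integers(2, 5)))
            codes = table.frame.map(lambda v: LABELS.index(v)).to_numpy()
            counts, _ = aggregate_raters(codes, n_cat=3)
            assert rel.fleiss_kappa(table).kappa == pytest.approx(
                fleiss_kappa(counts), abs=1e-12
            )

    def test_complete_case_restriction(self, rng):
        table = random_ratings(rng, 30, 4, missing_rate=0.3)
        pair = table.raters[:2]
        res = rel.fleiss_kappa(table, raters=pair)
        both = table.frame[pair].notna().all(axis=1)
        assert res.n_subjects_used == int(both.sum())

    def test_single_category_undefined(self):
        frame = pd.DataFrame(
            [["include", "include"]] * 5, columns=["a", "b"],
            index=[f"s{i}" for i in range(5)],
        )
        with pytest.raises(UndefinedStatisticError):
            rel.fleiss_kappa(RatingsTable(frame.astype(object)))

    def test_too_few_complete_cases(self):
        frame = pd.DataFrame(
            {"a": ["include", None, "exclude"], "b": [None, "include", "exclude"]},
            index=["s0", "s1", "s2"], dtype=object,
        )
        with pytest.raises(InsufficientDataError):
            rel.fleiss_kappa(RatingsTable(frame))

    def test_null_z_is_approximately_standard_normal(self):
        zs = []
        for i in range(200):
            table = random_ratings(np.random.default_rng(1000 + i), 40, 3)
            zs.append(rel.fleiss_kappa(table).z)
        assert abs(np.mean(zs)) < 0.2
        assert 0.75 < np.std(zs) < 1.3

    def test_label_permutation_invariance(self, rng):
        table = random_ratings(rng, 25, 3)
        swapped = RatingsTable(
            table.frame.replace({"include": "exclude", "exclude": "include"})
        )
        assert rel.fleiss_kappa(swapped).kappa == pytest.approx(
            rel.fleiss_kappa(table).kappa, abs=1e-12
        )


class TestCategorywiseKappa:
    def test_perfect_agreement(self, rng):
        labels = rng.choice(LABELS, size=30)
        frame = pd.DataFrame(
            {"a": labels, "b": labels, "c": labels}, index=[f"s{i}" for i in range(30)]
        )
        t = RatingsTable(frame.astype(object))
        for cat in LABELS:
            assert rel.categorywise_kappa(t, cat).kappa == pytest.approx(1.0)

    def test_matches_oracle_on_random_tables(self, rng):
        for _ in range(50):
            frame = random_ratings(rng, int(rng.integers(4, 12)), int(rng.integers(2, 5))).frame
            t = RatingsTable(frame)
            for cat in LABELS:
                counts = (frame == cat).sum().sum()
                if counts in (0, frame.size):
                    continue
                assert rel.categorywise_kappa(t, cat).kappa == pytest.approx(
                    categorywise_oracle(frame, cat), abs=1e-12
                )

    def test_overall_is_weighted_combination_of_categories(self, rng):
        # Fleiss' identity: kappa = sum_j p_j q_j kappa_j / sum_j p_j q_j
        for _ in range(20):
            frame = random_ratings(rng, 12, 3).frame
            t = RatingsTable(frame)
            if any((frame == c).sum().sum() in (0, frame.size) for c in LABELS):
                continue
            nr = len(frame.columns)
            ns = len(frame)
            pj = np.array([(frame == c).sum().sum() / (ns * nr) for c in LABELS])
            qj = 1 - pj
            ks = np.array([rel.categorywise_kappa(t, c).kappa for c in LABELS])
            combined = np.sum(pj * qj * ks) / np.sum(pj * qj)
            assert rel.fleiss_kappa(t).kappa == pytest.approx(combined, abs=1e-12)

    def test_category_never_used_undefined(self):
        frame = pd.DataFrame(
            [["include", "include"], ["exclude", "exclude"]] * 3,
            columns=["a", "b"], index=[f"s{i}" for i in range(6)],
        )
        with pytest.raises(UndefinedStatisticError):
            rel.categorywise_kappa(RatingsTable(frame.astype(object)), "uncertain")

    def test_disjoint_category_use_scores_at_or_below_zero(self):
        # one rater uses "uncertain" only where the other never does
        rows = []
        for i in range(12):
            if i % 4 == 0:
                rows.append(("uncertain", "include"))
            else:
                rows.append(("include", "include"))
        frame = pd.DataFrame(rows, columns=["a", "b"], index=[f"s{i}" for i in range(12)])
        res = rel.categorywise_kappa(RatingsTable(frame.astype(object)), "uncertain")
        assert res.kappa <= 0


class TestHolm:
    def test_worked_example(self):
        assert rel.holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert rel.holm_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones_stay_ones(self):
        assert rel.holm_adjust([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_adjusted_never_below_raw_and_capped(self, rng):
        p = rng.uniform(0, 1, size=10)
        adj = np.array(rel.holm_adjust(list(p)))
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_monotone_after_ordering(self, rng):
        p = rng.uniform(0, 1, size=8)
        adj = np.array(rel.holm_adjust(list(p)))
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            rel.holm_adjust([0.5, 1.5])


class TestPercentAgreement:
    def test_identical_raters_100(self, rng):
        labels = rng.choice(LABELS, size=15)
        frame = pd.DataFrame({"a": labels, "b": labels}, index=[f"s{i}" for i in range(15)])
        pa = rel.percent_agreement(RatingsTable(frame.astype(object)))
        assert pa.loc["a", "b"] == pytest.approx(100.0)

    def test_manual_ratio(self):
        # 13 shared subjects, 11 agreeing -> 100 * 11 / 13
        rows = [("include", "include")] * 11 + [("include", "exclude")] * 2
        frame = pd.DataFrame(rows, columns=["a", "b"], index=[f"s{i}" for i in range(13)])
        pa = rel.percent_agreement(RatingsTable(frame.astype(object)))
        assert pa.loc["a", "b"] == pytest.approx(100 * 11 / 13)

    def test_symmetry_and_nan_diagonal(self, rng):
        table = random_ratings(rng, 20, 4, missing_rate=0.2)
        pa = rel.percent_agreement(table)
        assert np.isnan(np.diag(pa.to_numpy().astype(float))).all()
        arr = pa.to_numpy().astype(float)
        np.testing.assert_allclose(arr, arr.T, equal_nan=True)


class TestKrippendorffAlpha:
    def test_perfect_agreement_with_missingness(self, rng):
        labels = rng.choice(LABELS, size=20)
        frame = pd.DataFrame(
            {r: labels for r in "abcd"}, index=[f"s{i}" for i in range(20)], dtype=object
        )
        frame.iloc[0, 0] = np.nan
        frame.iloc[5, 2] = np.nan
        res = rel.krippendorff_alpha(RatingsTable(frame), bootstrap_n=0)
        assert res.alpha == pytest.approx(1.0)

    def test_chance_labels_alpha_near_zero(self):
        table = random_ratings(np.random.default_rng(5), 4000, 3)
        res = rel.krippendorff_alpha(table, bootstrap_n=200, seed=0)
        assert res.ci_low < 0 < res.ci_high

    def test_fixed_table_with_missing_matches_oracle(self):
        frame = pd.DataFrame(
            [
                ["include", "include", "include"],
                ["include", "uncertain", None],
                ["exclude", "exclude", "exclude"],
                [None, "include", "include"],
                ["uncertain", "uncertain", "exclude"],
                ["exclude", "include", "exclude"],
            ],
            columns=["a", "b", "c"],
            index=[f"s{i}" for i in range(6)],
            dtype=object,
        )
        res = rel.krippendorff_alpha(RatingsTable(frame), bootstrap_n=0)
        assert res.alpha == pytest.approx(alpha_oracle(frame), abs=1e-12)

    def test_matches_oracle_on_random_missing_tables(self, rng):
        for _ in range(50):
            table = random_ratings(
                rng, int(rng.integers(4, 10)), int(rng.integers(2, 5)), missing_rate=0.25
            )
            if (table.frame.notna().sum(axis=1) >= 2).sum() < 2:
                continue
            res = rel.krippendorff_alpha(table, bootstrap_n=0)
            assert res.alpha == pytest.approx(alpha_oracle(table.frame), abs=1e-12)

    def test_removing_uncertain_cells_changes_basis(self, rng):
        # dropping every "uncertain" rating and recomputing must equal the
        # oracle on the pruned table (the 0.508 -> 0.694 style comparison)
        table = random_ratings(rng, 40, 4, missing_rate=0.1)
        pruned = table.frame.mask(table.frame == "uncertain")
        keep = pruned.notna().any(axis=1)
        pruned_table = RatingsTable(pruned.loc[keep])
        res = rel.krippendorff_alpha(pruned_table, bootstrap_n=0)
        assert res.alpha == pytest.approx(alpha_oracle(pruned.loc[keep]), abs=1e-12)

    def test_bootstrap_reproducible_under_seed(self, rng):
        table = random_ratings(rng, 30, 3, missing_rate=0.1)
        r1 = rel.krippendorff_alpha(table, bootstrap_n=100, seed=9)
        r2 = rel.krippendorff_alpha(table, bootstrap_n=100, seed=9)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.ci_high

    def test_ci_shrinks_with_more_subjects(self):
        from epiqc.synthetic import default_rater_panel, simulate_raters

        rng = np.random.default_rng(17)
        widths = []
        for n in (50, 500):
            true = list(rng.choice(LABELS, p=[0.7, 0.1, 0.2], size=n))
            table = simulate_raters(true, default_rater_panel(seed=3))
            res = rel.krippendorff_alpha(table, bootstrap_n=150, seed=1)
            widths.append(res.ci_high - res.ci_low)
        assert widths[1] < widths[0]

    def test_no_pairable_values_rejected(self):
        frame = pd.DataFrame(
            {"a": ["include", None], "b": [None, "exclude"]},
            index=["s0", "s1"], dtype=object,
        )
        with pytest.raises(InsufficientDataError):
            rel.krippendorff_alpha(RatingsTable(frame))


class TestMajorityClassification:
    def test_two_of_three_majority(self):
        frame = pd.DataFrame(
            [["include", "include", "exclude"]], columns=["a", "b", "c"], index=["s0"]
        )
        table, counts = rel.majority_classification(RatingsTable(frame.astype(object)))
        assert table.loc["s0", "labels"] == "include"
        assert counts["include"] == 1 and not table.loc["s0", "unresolved"]

    def test_three_way_split_unresolved(self):
        frame = pd.DataFrame(
            [["include", "uncertain", "exclude"]], columns=["a", "b", "c"], index=["s0"]
        )
        table, counts = rel.majority_classification(RatingsTable(frame.astype(object)))
        assert table.loc["s0", "unresolved"]
        assert sum(counts.values()) == 0

    def test_two_votes_among_four(self):
        frame = pd.DataFrame(
            [["uncertain", "uncertain", "include", "exclude"]],
            columns=list("abcd"), index=["s0"],
        )
        table, _ = rel.majority_classification(RatingsTable(frame.astype(object)))
        assert table.loc["s0", "labels"] == "uncertain"

    def test_double_majority_possible_with_four_raters(self):
        frame = pd.DataFrame(
            [["include", "include", "exclude", "exclude"]],
            columns=list("abcd"), index=["s0"],
        )
        table, counts = rel.majority_classification(RatingsTable(frame.astype(object)))
        assert table.loc["s0", "labels"] == "include;exclude"
        assert counts["include"] == 1 and counts["exclude"] == 1


class TestInterpretation:
    @pytest.mark.parametrize(
        "kappa,band",
        [
            (0.536, "moderate"),
            (0.731, "substantial"),
            (-0.1, "poor"),
            (0.0, "slight"),
            (0.20, "slight"),
            (0.21, "fair"),
            (0.60, "moderate"),
            (0.61, "substantial"),
            (0.81, "almost perfect"),
            (1.0, "almost perfect"),
        ],
    )
    def test_landis_koch_bands(self, kappa, band):
        assert rel.interpret_kappa(kappa) == band

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rel.interpret_kappa(1.5)


class TestPairwiseTable:
    def test_six_pairs_with_holm_family(self, rng):
        table = random_ratings(rng, 40, 4, missing_rate=0.15)
        out = rel.pairwise_kappa_table(table)
        assert len(out) == 6
        assert (out["p_adjusted"] >= out["p"] - 1e-15).all()
        assert set(out["category"]) == {"overall"}
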