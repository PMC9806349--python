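import numpy as np
import pytest

from pairfc.attention import init_params
from pairfc.cohort import LabeledScan
from pairfc.fewshot import (
    ConfusionCounts,
    Episode,
    build_episodes,
    classify_query,
    compute_metrics,
    evaluate,
    split_cohort,
)
from pairfc.similarity import pairwise_cosine, subject_similarity
from pairfc.attention import attend

from conftest import make_scan


def cohort_with_subjects(rng, n_nc=10, n_pt=10, scans_per_subject=1):
    cohort = []
    for label, prefix, count in (("NC", "NC", n_nc), ("patient", "PT", n_pt)):
        for i in range(count):
            for r in range(scans_per_subject):
                scan = make_scan(rng, label, f"{prefix}_{i}")
                scan.scan_id = f"{prefix}_{i}_r{r}"
                cohort.append(scan)
    return cohort


class TestSplitCohort:
    def test_counts_with_largest_remainder(self, rng):
        cohort = cohort_with_subjects(rng, 10, 10)
        tr, va, te = split_cohort(cohort, (0.6, 0.2, 0.2), seed=0)
        assert (len(tr), len(va), len(te)) == (12, 4, 4)

    def test_same_seed_identical_split(self, rng):
        cohort = cohort_with_subjects(rng, 8, 8)
        split1 = split_cohort(cohort, seed=3)
        split2 = split_cohort(cohort, seed=3)
        for part1, part2 in zip(split1, split2):
            assert [s.scan_id for s in part1] == [s.scan_id for s in part2]

    def test_subject_scans_stay_together(self, rng):
        cohort = cohort_with_subjects(rng, 6, 6, scans_per_subject=3)
        parts = split_cohort(cohort, seed=1)
        assert sum(len(p) for p in parts) == len(cohort)
        for subject in {s.subject_id for s in cohort}:
            homes = [
                i for i, part in enumerate(parts)
                if any(s.subject_id == subject for s in part)
            ]
            assert len(homes) == 1

    def test_stratification_by_class(self, rng):
        cohort = cohort_with_subjects(rng, 10, 5)
        tr, va, te = split_cohort(cohort, seed=2)
        for part, expected_nc, expected_pt in ((tr, 6, 3), (va, 2, 1), (te, 2, 1)):
            labels = [s.label for s in part]
            assert labels.count("NC") == expected_nc
            assert labels.count("patient") == expected_pt

    def test_class_too_small_rejected(self, rng):
        cohort = cohort_with_subjects(rng, 8, 2)
        with pytest.raises(ValueError, match="too few"):
            split_cohort(cohort, seed=0)

    def test_bad_fractions_rejected(self, rng):
        cohort = cohort_with_subjects(rng, 4, 4)
        with pytest.raises(ValueError, match="fractions"):
            split_cohort(cohort, (0.5, 0.5, 0.5), seed=0)


class TestBuildEpisodes:
    def test_support_and_query_sizes(self, rng):
        cohort = cohort_with_subjects(rng, 8, 8)
        episodes = build_episodes(cohort, n_shot=5, n_query=2, n_episodes=7, seed=0)
        assert len(episodes) == 7
        for ep in episodes:
            assert len(ep.support) == 10  # 2-way 5-shot
            assert len(ep.query) == 4

    def test_determinism(self, rng):
        cohort = cohort_with_subjects(rng, 7, 7)
        eps1 = build_episodes(cohort, 3, 2, 5, seed=4)
        eps2 = build_episodes(cohort, 3, 2, 5, seed=4)
        for e1, e2 in zip(eps1, eps2):
            assert [s.scan_id for s in e1.support] == [s.scan_id for s in e2.support]
            assert [s.scan_id for s in e1.query] == [s.scan_id for s in e2.query]

    def test_no_scan_in_both_support_and_query(self, rng):
        cohort = cohort_with_subjects(rng, 6, 6)
        for ep in build_episodes(cohort, 3, 3, 10, seed=1):
            assert not ({s.scan_id for s in ep.support} & {s.scan_id for s in ep.query})

    def test_class_with_no_query_headroom_rejected(self, rng):
        cohort = cohort_with_subjects(rng, 5, 8)
        with pytest.raises(ValueError, match="support plus at least one query"):
            build_episodes(cohort, n_shot=5, n_query=1, n_episodes=1, seed=0)

    def test_unbalanced_support_rejected(self, rng):
        support = [make_scan(rng, "NC", "a"), make_scan(rng, "NC", "b")]
        with pytest.raises(ValueError, match="equal counts"):
            Episode(support=support, query=[make_scan(rng, "patient", "c")])


class TestClassifyQuery:
    def test_dominant_similarity_wins(self, rng):
        query = make_scan(rng, "patient", "Q")
        twin = make_scan(rng, "patient", "S1")
        twin.fcm.series = query.fcm.series.copy()
        others = [make_scan(rng, "NC", f"N{i}") for i in range(1)]
        episode = Episode(support=[twin] + others, query=[query])
        params = init_params(query.fcm.n_windows, seed=0)
        assert classify_query(query, episode, params) == "patient"

    def test_exact_tie_goes_to_nc(self, rng):
        query = make_scan(rng, "patient", "Q")
        s_nc = make_scan(rng, "NC", "N")
        s_pt = make_scan(rng, "patient", "P")
        s_pt.fcm.series = s_nc.fcm.series.copy()  # identical supports, equal sims
        episode = Episode(support=[s_nc, s_pt], query=[query])
        params = init_params(query.fcm.n_windows, seed=0)
        assert classify_query(query, episode, params) == "NC"

    def test_agrees_with_bruteforce_support_loop(self, rng):
        cohort = cohort_with_subjects(rng, 4, 4)
        episode = build_episodes(cohort, n_shot=3, n_query=1, n_episodes=1, seed=2)[0]
        params = init_params(cohort[0].fcm.n_windows, seed=1)
        for query in episode.query:
            wq = attend(query.fcm, params)
            sims = {}
            for s in episode.support:
                sim = subject_similarity(
                    pairwise_cosine(wq, attend(s.fcm, params)), "mean"
                ).value
                sims.setdefault(s.label, []).append(sim)
            means = {lab: np.mean(v) for lab, v in sims.items()}
            expected = max(sorted(means), key=lambda lab: (means[lab], lab == "NC"))
            assert classify_query(query, episode, params) == expected


class TestComputeMetrics:
    def test_perfect_classifier(self):
        report = compute_metrics(ConfusionCounts(tp=5, tn=5))
        assert (report.acc, report.spe, report.ppv, report.npv) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_computed_table(self):
        report = compute_metrics(ConfusionCounts(tp=3, tn=4, fp=1, fn=2))
        assert report.acc == pytest.approx(0.7)
        assert report.spe == pytest.approx(0.8)
        assert report.ppv == pytest.approx(0.75)
        assert report.npv == pytest.approx(2 / 3)

    def test_zero_denominator_yields_nan_marker(self):
        report = compute_metrics(ConfusionCounts(tp=0, tn=3, fp=0, fn=2))
        assert np.isnan(report.ppv)
        assert not np.isnan(report.acc)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            compute_metrics(ConfusionCounts())

    def test_random_tables_match_hand_formulas_and_acc_bounds(self, rng):
        from oracles import metrics_by_hand

        for _ in range(50):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 20, size=4))
            if tp + tn + fp + fn == 0:
                continue
            report = compute_metrics(ConfusionCounts(tp, tn, fp, fn))
            by_hand = metrics_by_hand(tp, tn, fp, fn)
            for ours, ref in zip(
                (report.acc, report.spe, report.ppv, report.npv),
                (by_hand["ACC"], by_hand["SPE"], by_hand["PPV"], by_hand["NPV"]),
            ):
                assert (np.isnan(ours) and np.isnan(ref)) or ours == pytest.approx(ref)
            # pooled accuracy is bounded by the per-class accuracies
            if tp + fn > 0 and tn + fp > 0:
                sens = tp / (tp + fn)
                spec = tn / (tn + fp)
                assert min(sens, spec) - 1e-12 <= report.acc <= max(sens, spec) + 1e-12


class TestEvaluate:
    def test_pooled_counts_equal_sum_of_episode_counts(self, rng):
        cohort = cohort_with_subjects(rng, 6, 6)
        params = init_params(cohort[0].fcm.n_windows, seed=0)
        result = evaluate(cohort, params, n_shot=3, n_query=2, n_episodes=8, seed=3)
        total = ConfusionCounts()
        for c in result.per_episode_counts:
            total = total + c
        assert total.tp == result.pooled.counts.tp
        assert total.total == result.pooled.counts.total == 8 * 4
        assert 0.0 <= result.pooled.acc <= 1.0
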