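"""Pair construction, similarity-guided splitting and RF classification."""

import numpy as np
import pytest

from graphtcr import (BindingPair, ClassifierConfig, evaluate_auroc,
                      filter_epitopes, generate_negatives, one_hot_encode,
                      pair_features, similarity_split, train_classifier)
from graphtcr.classify import cross_validate, downsample_experiment


def _pairs(spec):
    """spec: list of (tcr, epitope) tuples -> positive BindingPairs."""
    return [BindingPair(tcr=t, epitope=e, label=1, pair_id=i)
            for i, (t, e) in enumerate(spec)]


def brute_force_auroc(scores, labels):
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestFilter:
    def test_boundary_at_min_tcrs(self):
        pairs = _pairs([(f"CASS{i:04d}F".replace("0", "G").replace("1", "A")
                         .replace("2", "S").replace("3", "T").replace("4", "V")
                         .replace("5", "L").replace("6", "I").replace("7", "P")
                         .replace("8", "W").replace("9", "Y"), "EPIA")
                        for i in range(999)])
        assert filter_epitopes(pairs, min_tcrs=1000) == []
        pairs_1000 = pairs + _pairs([("CASSWWWWF", "EPIA")])
        kept = filter_epitopes(pairs_1000, min_tcrs=1000)
        assert len(kept) == 1000

    def test_min_one_is_identity(self):
        pairs = _pairs([("CASSF", "AAA"), ("CASTF", "BBB")])
        assert filter_epitopes(pairs, min_tcrs=1) == pairs

    def test_counts_distinct_tcrs_only(self):
        pairs = _pairs([("CASSF", "AAA")] * 5)
        assert filter_epitopes(pairs, min_tcrs=2) == []


class TestOneHot:
    def test_counting(self):
        v = one_hot_encode("CAS", 5)
        assert v.shape == (100,) and v.sum() == 3

    def test_positions(self):
        v = one_hot_encode("A", 1)
        assert v[0] == 1 and v.sum() == 1  # A is rank 0
        w = one_hot_encode("C", 1)
        assert ((v - w) ** 2).sum() == 2

    def test_too_long_rejected(self):
        with pytest.raises(ValueError):
            one_hot_encode("CASSF", 3)


class TestSplit:
    def _repertoire(self, n_per=50, seed=0):
        from graphtcr import SimulationConfig, simulate_repertoire
        pairs, _ = simulate_repertoire(SimulationConfig(
            n_epitopes=3, tcrs_per_epitope=n_per, seed=seed))
        return pairs

    def test_disjoint_and_quota(self):
        pairs = self._repertoire()
        split = similarity_split(pairs, test_fraction=0.2, seed=1)
        assert split.train_ids.isdisjoint(split.test_ids)
        assert len(split.train_ids | split.test_ids) == len(pairs)
        n_test = len(split.test_ids)
        assert 0.1 * len(pairs) <= n_test <= 0.35 * len(pairs)

    def test_duplicate_strings_same_side(self):
        base = self._repertoire(n_per=20)
        # duplicate a CDR3 string within its epitope under a fresh id
        dup = BindingPair(tcr=base[0].tcr, epitope=base[0].epitope, label=1,
                          pair_id=10_000)
        pairs = base + [dup]
        split = similarity_split(pairs, test_fraction=0.3, seed=5)
        sides = [("test" if p.pair_id in split.test_ids else "train")
                 for p in pairs if p.tcr == base[0].tcr
                 and p.epitope == base[0].epitope]
        assert len(set(sides)) == 1

    def test_no_string_leakage_within_epitope(self):
        pairs = self._repertoire()
        split = similarity_split(pairs, test_fraction=0.2, seed=3)
        for epi in {p.epitope for p in pairs}:
            train_tcrs = {p.tcr for p in pairs
                          if p.epitope == epi and p.pair_id in split.train_ids}
            test_tcrs = {p.tcr for p in pairs
                         if p.epitope == epi and p.pair_id in split.test_ids}
            assert train_tcrs.isdisjoint(test_tcrs)

    def test_single_tcr_epitope_flagged(self):
        pairs = _pairs([("CASSAAAAF", "E1"), ("CASSWWWWF", "E2"),
                        ("CASSWWWYF", "E2"), ("CASSWWYYF", "E2"),
                        ("CASSWYYYF", "E2"), ("CASSYYYYF", "E2")])
        split = similarity_split(pairs, test_fraction=0.2, seed=0)
        assert "E1" in split.unsplittable_epitopes
        assert pairs[0].pair_id in split.train_ids

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            similarity_split(self._repertoire(), test_fraction=1.5)


class TestNegatives:
    def _positives(self):
        return _pairs([("CASSAF", "E1"), ("CASSCF", "E1"),
                       ("CASSDF", "E2"), ("CASSEF", "E2"),
                       ("CASSFF", "E3"), ("CASSGF", "E3")])

    def test_ratio_and_validity(self):
        pos = self._positives()
        neg = generate_negatives(pos, ratio=1.0, seed=0)
        assert len(neg) == len(pos)
        pos_set = {(p.tcr, p.epitope) for p in pos}
        assert all((n.tcr, n.epitope) not in pos_set for n in neg)
        assert all(n.label == 0 and n.origin == "shuffled" for n in neg)
        assert len({(n.tcr, n.epitope) for n in neg}) == len(neg)

    def test_single_epitope_rejected(self):
        pos = _pairs([("CASSAF", "E1"), ("CASSCF", "E1")])
        with pytest.raises(ValueError):
            generate_negatives(pos, strategy="shuffle")

    def test_swap_groups_respects_groups(self):
        pos = self._positives()
        groups = {"E1": "g1", "E2": "g1", "E3": "g2"}
        neg = generate_negatives(pos, strategy="swap_groups", ratio=0.5,
                                 seed=1, groups=groups)
        cognate = {}
        for p in pos:
            cognate.setdefault(p.tcr, set()).add(groups[p.epitope])
        for n in neg:
            assert groups[n.epitope] not in cognate[n.tcr]
            assert n.origin == "swapped"

    def test_deterministic(self):
        pos = self._positives()
        a = generate_negatives(pos, seed=7)
        b = generate_negatives(pos, seed=7)
        assert [(n.tcr, n.epitope) for n in a] == [(n.tcr, n.epitope) for n in b]


class TestFeaturesAndForest:
    def test_concatenation(self):
        a, b = np.arange(4.0), np.arange(4.0) + 10
        v = pair_features(a, b)
        assert v.shape == (8,) and (v[:4] == a).all() and (v[4:] == b).all()
        assert not np.array_equal(pair_features(a, b), pair_features(b, a))
        with pytest.raises(ValueError):
            pair_features(np.zeros(3), np.zeros(4))

    def test_separable_data_and_depth_sweep(self, rng):
        X = np.vstack([rng.normal(0, 1, (50, 6)), rng.normal(8, 1, (50, 6))])
        y = np.repeat([0, 1], 50)
        clf = train_classifier(X, y, ClassifierConfig(n_trees=50, seed=0))
        r = evaluate_auroc(clf.predict_proba(X)[:, 1], y)
        assert r.auroc >= 0.99
        for depth in range(1, 16):
            c = train_classifier(X, y, ClassifierConfig(n_trees=10,
                                                        max_depth=depth, seed=0))
            assert np.isfinite(c.predict_proba(X)).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_classifier(np.zeros((5, 2)), np.zeros(5))


class TestAuroc:
    def test_worked_example(self):
        r = evaluate_auroc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0])
        assert r.auroc == pytest.approx(0.75)

    def test_degenerate_cases(self):
        assert evaluate_auroc([1, 1, 0, 0], [1, 1, 0, 0]).auroc == 1.0
        assert evaluate_auroc([0.5] * 6, [1, 0, 1, 0, 1, 0]).auroc == 0.5

    def test_matches_brute_force(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 50))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            assert evaluate_auroc(scores, labels).auroc == pytest.approx(
                brute_force_auroc(scores, labels))

    def test_curve_endpoints(self):
        r = evaluate_auroc([0.9, 0.1, 0.8, 0.2], [1, 0, 1, 0])
        assert (r.fpr[0], r.tpr[0]) == (0, 0)
        assert (r.fpr[-1], r.tpr[-1]) == (1, 1)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_auroc([0.5, 0.6], [1, 1])


class TestComposedExperiments:
    def test_cross_validate_folds_partition(self):
        from graphtcr import SimulationConfig, simulate_repertoire
        pairs, _ = simulate_repertoire(SimulationConfig(
            n_epitopes=2, tcrs_per_epitope=20, seed=2))
        table = cross_validate(pairs, k_folds=3, grid=[(2, 8)], epochs=2,
                               seed=0, classifier=ClassifierConfig(n_trees=20, seed=0))
        assert set(table.columns) >= {"wl_iterations", "dimensions", "mean_auroc"}
        assert table.n_folds.iloc[0] == 3
        assert 0 <= table.mean_auroc.iloc[0] <= 1
        with pytest.raises(ValueError):
            cross_validate(pairs, k_folds=1)

    def test_downsample_ratio_one_and_determinism(self):
        from graphtcr import SimulationConfig, simulate_repertoire
        pairs, _ = simulate_repertoire(SimulationConfig(
            n_epitopes=2, tcrs_per_epitope=25, seed=2))
        kw = dict(wl_iterations=2, dimensions=8, epochs=2,
                  classifier=ClassifierConfig(n_trees=20, seed=0))
        t1 = downsample_experiment(pairs, [0.5, 1.0], seed=3, **kw)
        t2 = downsample_experiment(pairs, [0.5, 1.0], seed=3, **kw)
        assert t1.auroc.tolist() == t2.auroc.tolist()
        assert (t1.ratio == [0.5, 1.0]).all()
        with pytest.raises(ValueError):
            downsample_experiment(pairs, [0.0], seed=0, **kw)
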