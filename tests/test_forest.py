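import subprocess
import textwrap

import numpy as np
import pytest

from agosort import (
    compare_conditions,
    encode_features,
    margins,
    train_forest,
    variable_importance,
    wilcoxon_rank_sum,
)
from agosort.duplex import DuplexPattern, UNPAIRED, WC, WOBBLE
from agosort.forest import FeatureMatrix, ForestResult, SEQUENCE_ALPHABET, first_position_only
from tests.conftest import make_confidence_set

BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}


def seq_matrix(seqs, length=24):
    X = np.array([[BASE_CODE[c] for c in s.ljust(length, "N")[:length]] for s in seqs])
    return FeatureMatrix(X=X, alphabet=SEQUENCE_ALPHABET, positions=list(range(1, length + 1)),
                         mode="sequence")


class TestEncodeFeatures:
    def test_sequence_mode_pads_with_n(self, three_class_cset):
        fm = encode_features(three_class_cset, mode="sequence")
        assert fm.X.shape[1] == 24
        n_code = SEQUENCE_ALPHABET.index("N")
        assert (fm.X[:, 21:] == n_code).all()  # 21-mers padded at 22-24

    def test_pairing_mode_pads_unbound(self, three_class_cset):
        patterns = {
            e.id: DuplexPattern(states=[WC] * 18 + [WOBBLE], n_mismatches=0, max_bulge=0)
            for e in three_class_cset.entries
        }
        fm = encode_features(three_class_cset, mode="pairing", patterns=patterns)
        assert fm.X.shape[1] == 24
        assert (fm.X[:, 19:] == 1).all()  # unbound code
        assert (fm.X[:, 18] == 2).all()  # wobble code

    def test_exclude_first_drops_one_column(self, three_class_cset):
        fm = encode_features(three_class_cset, mode="sequence", include_first=False)
        assert fm.X.shape[1] == 23
        assert fm.positions[0] == 2

    def test_unknown_mode_rejected(self, three_class_cset):
        with pytest.raises(ValueError, match="mode"):
            encode_features(three_class_cset, mode="pca")


class TestTrainForest:
    def test_perfectly_separable_single_feature(self):
        labels = ["AGO1"] * 20 + ["AGO2"] * 20 + ["AGO5"] * 20
        X = np.array([[0]] * 20 + [[1]] * 20 + [[2]] * 20)
        res = train_forest(X, labels, n_trees=100, sampsize=10, seed=0)
        assert res.oob_accuracy >= 0.95

    def test_same_seed_identical_result(self, three_class_cohort):
        seqs, labels = three_class_cohort
        fm = seq_matrix(seqs)
        r1 = train_forest(fm, labels, n_trees=30, seed=5)
        r2 = train_forest(fm, labels, n_trees=30, seed=5)
        assert np.array_equal(r1.oob_votes, r2.oob_votes)
        assert r1.oob_accuracy == r2.oob_accuracy

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            train_forest(np.zeros((3, 2), dtype=int), ["AGO1", "AGO1", "AGO2"])

    def test_vote_fractions_sum_to_one(self, three_class_cohort):
        seqs, labels = three_class_cohort
        res = train_forest(seq_matrix(seqs), labels, n_trees=50, seed=1)
        fr = res.vote_fractions()
        covered = res.oob_tree_counts > 0
        np.testing.assert_allclose(fr[covered].sum(axis=1), 1.0)

    def test_shuffled_balanced_classes_near_chance(self):
        """Class-shuffled OOB accuracy over repeated runs sits at the
        three-class chance level (1/3) within Monte-Carlo error."""
        rng = np.random.default_rng(11)
        labels = ["AGO1"] * 39 + ["AGO2"] * 39 + ["AGO5"] * 39
        accs = []
        for r in range(15):
            X = rng.integers(0, 4, size=(117, 24))
            res = train_forest(X, labels, n_trees=100, seed=r)
            accs.append(res.oob_accuracy)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 1 / 3) <= 3 * max(se, 0.01)

    def test_oob_majority_matches_balanced_bootstrap_oracle(self):
        """On a one-feature problem the forest must agree with a brute-force
        oracle: per tree, predict the in-bag majority of the sample's
        category (fixed class order on ties), aggregated over OOB trees."""
        rng = np.random.default_rng(3)
        n_per = 30
        labels = ["AGO1"] * n_per + ["AGO2"] * n_per + ["AGO5"] * n_per
        y = np.repeat([0, 1, 2], n_per)
        # category informative but noisy
        X = np.where(rng.random(90) < 0.7, y, rng.integers(0, 3, size=90)).reshape(-1, 1)
        res = train_forest(X, labels, n_trees=400, sampsize=15, seed=4)

        oracle_rng = np.random.default_rng(99)
        votes = np.zeros((90, 3), dtype=int)
        for _ in range(400):
            inbag = np.concatenate(
                [oracle_rng.choice(np.flatnonzero(y == c), size=15, replace=True) for c in range(3)]
            )
            oob = np.setdiff1d(np.arange(90), inbag)
            for i in oob:
                cat = X[i, 0]
                members = inbag[X[inbag, 0] == cat]
                if len(members):
                    pred = np.argmax(np.bincount(y[members], minlength=3))
                else:
                    pred = np.argmax(np.bincount(y[inbag], minlength=3))
                votes[i, pred] += 1
        oracle_pred = np.argmax(votes, axis=1)
        oracle_acc = np.mean(oracle_pred == y)
        assert abs(res.oob_accuracy - oracle_acc) < 0.07

    def test_matches_reference_r_random_forest(self, tmp_path, three_class_cohort):
        """Cross-check OOB accuracy against the classical R randomForest
        implementation with a stratified balanced bootstrap."""
        pytest.importorskip("pandas")
        seqs, labels = three_class_cohort
        fm = seq_matrix(seqs)
        mine = train_forest(fm, labels, n_trees=400, sampsize=20, seed=0)

        csv = tmp_path / "data.csv"
        with open(csv, "w") as fh:
            fh.write(",".join(f"p{i}" for i in range(24)) + ",label\n")
            for row, lab in zip(fm.X, labels):
                fh.write(",".join("ACGUN"[v] for v in row) + f",{lab}\n")
        script = tmp_path / "rf.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(randomForest))
            set.seed(1)
            d <- read.csv("{csv}", stringsAsFactors=TRUE)
            X <- d[, 1:24]
            X[] <- lapply(X, factor, levels=c("A","C","G","U","N"))
            y <- factor(d$label)
            fit <- randomForest(X, y, ntree=400, sampsize=c(20,20,20), strata=y)
            cat(mean(fit$predicted == y, na.rm=TRUE), "\\n")
        """))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        r_acc = float(out.stdout.strip().split()[-1])
        assert abs(mine.oob_accuracy - r_acc) < 0.08


class TestMargins:
    def make_result(self, votes, classes=("AGO1", "AGO2", "AGO5")):
        votes = np.asarray(votes)
        return ForestResult(
            classes=list(classes),
            trees=[],
            oob_votes=votes,
            oob_tree_counts=votes.sum(axis=1),
            oob_accuracy=0.0,
            n_trees=int(votes.sum()),
        )

    @pytest.mark.parametrize(
        "votes,label,expected",
        [
            ([[6, 3, 1]], "AGO1", 0.3),
            ([[10, 0, 0]], "AGO1", 1.0),
            ([[2, 8, 0]], "AGO1", -0.6),
        ],
    )
    def test_margin_values(self, votes, label, expected):
        res = self.make_result(votes)
        assert margins(res, [label])[0] == pytest.approx(expected)

    def test_never_oob_sample_excluded(self):
        res = self.make_result([[5, 5, 0], [0, 0, 0]])
        assert len(margins(res, ["AGO1", "AGO2"])) == 1


class TestVariableImportance:
    def test_constant_feature_zero_importance(self):
        labels = ["AGO1"] * 25 + ["AGO2"] * 25
        X = np.zeros((50, 3), dtype=int)
        X[:, 0] = np.repeat([0, 1], 25)
        res = train_forest(X, labels, n_trees=80, sampsize=15, seed=2)
        imp = variable_importance(res, X, labels, seed=0)
        assert imp[1] == pytest.approx(0.0)
        assert imp[2] == pytest.approx(0.0)
        # with mtry=1 only ~1/3 of trees split on the informative feature
        assert imp[0] > 0.1

    def test_planted_informative_feature_is_argmax(self, rng):
        labels = ["AGO1"] * 40 + ["AGO2"] * 40
        y = np.repeat([0, 1], 40)
        X = rng.integers(0, 4, size=(80, 10))
        X[:, 6] = np.where(rng.random(80) < 0.9, y, 1 - y)
        res = train_forest(X, labels, n_trees=150, sampsize=20, seed=3)
        imp = variable_importance(res, X, labels, seed=1)
        assert np.argmax(imp) == 6


class TestWilcoxon:
    def test_exact_small_sample(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_p_one(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_symmetric_in_arguments(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(0.5, size=40)
        assert wilcoxon_rank_sum(x, y) == pytest.approx(wilcoxon_rank_sum(y, x))


class TestCompareConditions:
    def test_identical_conditions_median_p_one(self, three_class_cohort):
        seqs, labels = three_class_cohort
        fm = seq_matrix(seqs)
        res = compare_conditions(fm, fm, labels, n_runs=3, seed=0, n_trees=40)
        assert res["median_p"] == pytest.approx(1.0)

    def test_signal_beats_class_shuffled(self, three_class_cohort):
        seqs, labels = three_class_cohort
        fm = seq_matrix(seqs)
        res = compare_conditions(fm, fm, labels, n_runs=11, seed=1, shuffle="b", n_trees=100)
        assert res["median_p"] < 0.05
        assert res["mean_acc_a"] > res["mean_acc_b"]

    def test_partial_features_ordering(self):
        """If the class signal lives only beyond position 1, the
        all-but-first condition must outperform first-only."""
        rng = np.random.default_rng(8)
        y = np.repeat([0, 1, 2], 30)
        labels = ["AGO1"] * 30 + ["AGO2"] * 30 + ["AGO5"] * 30
        X = rng.integers(0, 4, size=(90, 24))
        for pos in (3, 7):
            X[:, pos] = np.where(rng.random(90) < 0.85, y, rng.integers(0, 3, 90))
        X[:, 0] = rng.integers(0, 4, size=90)
        fm_all = FeatureMatrix(X=X, alphabet=SEQUENCE_ALPHABET,
                               positions=list(range(1, 25)), mode="sequence")
        fm_nofirst = FeatureMatrix(X=X[:, 1:], alphabet=SEQUENCE_ALPHABET,
                                   positions=list(range(2, 25)), mode="sequence")
        fm_first = first_position_only(fm_all)
        res = compare_conditions(fm_nofirst, fm_first, labels, n_runs=5, seed=2, n_trees=100)
        assert res["mean_acc_a"] > res["mean_acc_b"]
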