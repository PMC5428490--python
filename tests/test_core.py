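import math

import numpy as np
import pytest
from scipy import stats

from heterosis import (
    RelationConfig,
    assign_lp_hp,
    class_union_counts,
    classify_gene,
    classify_transcriptome,
    fold_change,
    mpv,
    nonadditivity_test,
    relation,
    updown_ratio,
)
from heterosis.core import ClassSummary, Relation
from heterosis.errors import ConfigError, InsufficientReplicationError

from conftest import make_trio


@pytest.mark.parametrize(
    "a,b,c,expected",
    [(10, 5, 0, 2.0), (0, 0, 1, 1.0), (19, 10, 0, 1.9), (0, 0, 0, 1.0), (3, 7, 1, 2.0)],
)
def test_fold_change(a, b, c, expected):
    assert fold_change(a, b, c) == pytest.approx(expected)
    assert fold_change(b, a, c) == pytest.approx(expected)  # symmetric


@pytest.mark.parametrize(
    "x,y,expected",
    [
        (10, 40, Relation.GREATER),
        (10, 19, Relation.EQUAL),
        (40, 10, Relation.LESS),
        (10, 20, Relation.GREATER),  # exactly two-fold counts as different
        (7, 7, Relation.EQUAL),
    ],
)
def test_relation(x, y, expected, exact_cfg):
    assert relation(x, y, exact_cfg) is expected


@pytest.mark.parametrize(
    "pA,pB,expected",
    [
        (100, 10, ("parentB", 10, 100)),
        (10, 100, ("parentA", 10, 100)),
        (7, 7, ("parentA", 7, 7)),  # tie labels parentA as LP
    ],
)
def test_assign_lp_hp(pA, pB, expected):
    assert assign_lp_hp(pA, pB) == expected


@pytest.mark.parametrize(
    "pA,pB,H,expected",
    [
        (10, 100, 40, 1),   # LP < H < HP
        (100, 10, 40, 1),   # parent swap of the above
        (10, 100, 95, 2),   # LP < H = HP
        (10, 100, 12, 3),   # LP = H < HP
        (10, 12, 11, 4),    # all within two-fold
        (10, 100, 500, 5),  # LP < HP < H
        (10, 12, 50, 6),    # parents equal, hybrid above
        (10, 100, 2, 7),    # H < LP < HP
        (10, 12, 2, 8),     # H < LP = HP
    ],
)
def test_classify_gene_table_rows(pA, pB, H, expected, exact_cfg):
    assert classify_gene(pA, pB, H, exact_cfg) == expected


@pytest.mark.parametrize("pA,pB,expected", [(10, 20, 15.0), (7, 7, 7.0), (0, 0, 0.0)])
def test_mpv(pA, pB, expected):
    assert mpv(pA, pB) == expected


class TestNonadditivityTest:
    def test_hybrid_exactly_at_mpv(self):
        p, na = nonadditivity_test([15, 15, 15], [10, 10, 10], [20, 20, 20])
        assert p == 1.0 and na is False

    def test_matches_hand_computed_welch_statistic(self):
        """p equals the Welch t-test evaluated from first principles."""
        h = np.array([40.1, 39.8, 40.3])
        a = np.array([10.2, 9.9, 10.1])
        b = np.array([20.1, 19.8, 20.0])
        m = (a + b) / 2
        # direct formula evaluation: Welch statistic and Satterthwaite df
        vh, vm = h.var(ddof=1) / h.size, m.var(ddof=1) / m.size
        t = (h.mean() - m.mean()) / math.sqrt(vh + vm)
        df = (vh + vm) ** 2 / (vh**2 / (h.size - 1) + vm**2 / (m.size - 1))
        expected = 2.0 * stats.t.sf(abs(t), df)
        p, na = nonadditivity_test(h, a, b)
        assert p == pytest.approx(expected, abs=1e-10)
        assert na is True

    def test_unequal_parent_replication_uses_one_sample_test(self):
        p, na = nonadditivity_test([15, 15], [10, 10, 10], [20, 20])
        assert p == 1.0 and na is False  # hybrid constant at the scalar MPV

    def test_one_sample_path_matches_scipy(self):
        h = [14.2, 15.1, 15.6]
        p, _ = nonadditivity_test(h, [10, 10, 10], [20, 20])
        assert p == pytest.approx(stats.ttest_1samp(h, 15.0).pvalue, abs=1e-12)

    def test_zero_variance_unequal_means(self):
        p, na = nonadditivity_test([30, 30, 30], [10, 10, 10], [20, 20, 20])
        assert p == 0.0 and na is True

    @pytest.mark.parametrize(
        "h,a,b", [([15], [10, 10], [20, 20]), ([15, 15], [10], [20, 20])]
    )
    def test_insufficient_replication(self, h, a, b):
        with pytest.raises(InsufficientReplicationError):
            nonadditivity_test(h, a, b)


class TestClassifyTranscriptome:
    def test_zero_noise_recovers_engineered_classes(self, exact_cfg):
        # one gene per class, means straight from the class templates (s=4)
        s = 4.0
        means = {
            1: (1, s * s, s), 2: (1, s, s), 3: (1, s, 1), 4: (1, 1, 1),
            5: (1, s, s * s), 6: (1, 1, s), 7: (s, s * s, 1), 8: (s, s, 1),
        }
        rows = [[10 * lp, 10 * hp, 10 * h] for lp, hp, h in means.values()]
        xs = make_trio(np.array(rows))
        records, summary = classify_transcriptome(xs, exact_cfg)
        assert [r.class_id for r in records] == list(means)
        assert summary.total_genes == 8
        assert all(summary.total_count[c] == 1 for c in range(1, 9))

    def test_summary_partitions_genes(self, exact_cfg):
        rng = np.random.default_rng(11)
        xs = make_trio(rng.uniform(0, 200, size=(120, 3)))
        records, summary = classify_transcriptome(xs, exact_cfg)
        assert class_union_counts(summary, range(1, 9)) == 120 == len(records)
        for c in range(1, 9):
            assert summary.nonadditive_count[c] <= summary.total_count[c]

    def test_fdr_call_is_no_more_liberal(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(10, 100, size=(60, 3))
        reps = np.repeat(base, 3, axis=1) * rng.lognormal(0, 0.1, size=(60, 9))
        xs = make_trio(base)
        xs.values = reps
        _, plain = classify_transcriptome(xs)
        _, adjusted = classify_transcriptome(xs, fdr=True)
        assert adjusted.nonadditive_total <= plain.nonadditive_total


class TestClassUnionCounts:
    def test_named_unions(self):
        summary = ClassSummary(
            tissue="t", stage="s",
            total_count={1: 5, 2: 10, 3: 0, 4: 50, 5: 7, 6: 3, 7: 2, 8: 1},
            nonadditive_count={},
        )
        assert class_union_counts(summary, {2, 5, 6}) == 20
        assert class_union_counts(summary, {7, 8}) == 3
        assert class_union_counts(summary, set()) == 0

    def test_bad_class_id(self):
        summary = ClassSummary("t", "s", {}, {})
        with pytest.raises(ValueError):
            class_union_counts(summary, {0, 9})


class TestUpdownRatio:
    def _engineered(self, n_up, n_down, n_flat):
        rows = (
            [[10, 10, 100]] * n_up + [[100, 100, 10]] * n_down + [[50, 50, 50]] * n_flat
        )
        return make_trio(np.array(rows, dtype=float))

    def test_headline_ratio(self, exact_cfg):
        xs = self._engineered(27, 2, 5)
        n_up, n_down, ratio = updown_ratio(xs, "hybrid", "parentA", cfg=exact_cfg)
        assert (n_up, n_down) == (27, 2)
        assert ratio == pytest.approx(13.5)

    def test_category_ratio(self, exact_cfg):
        xs = self._engineered(51, 1, 0)
        assert updown_ratio(xs, "hybrid", "parentA", cfg=exact_cfg)[2] == 51

    def test_no_down_regulation_is_nan(self, exact_cfg):
        xs = self._engineered(0, 0, 4)
        n_up, n_down, ratio = updown_ratio(xs, "hybrid", "parentA", cfg=exact_cfg)
        assert (n_up, n_down) == (0, 0) and math.isnan(ratio)

    def test_gene_subset(self, exact_cfg):
        xs = self._engineered(3, 1, 0)
        n_up, n_down, _ = updown_ratio(
            xs, "hybrid", "parentA", gene_set={"g1", "g4"}, cfg=exact_cfg
        )
        assert (n_up, n_down) == (1, 1)
        with pytest.raises(ValueError, match="gX"):
            updown_ratio(xs, "hybrid", "parentA", gene_set={"gX"}, cfg=exact_cfg)


def test_relation_config_validation():
    with pytest.raises(ConfigError):
        RelationConfig(fold_threshold=1.0)
    with pytest.raises(ConfigError):
        RelationConfig(pseudocount=-1)
    with pytest.raises(ConfigError):
        RelationConfig(alpha=1.5)
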