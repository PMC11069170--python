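"""Distance/contact evaluation statistics against hand-worked oracles."""

import math

import numpy as np
import pytest

from freeprotmap.metrics import (
    SEPARATION_CLASSES,
    channel_correlation,
    classifier_metrics,
    contact_from_distance,
    dataset_summary,
    distance_metrics,
    topk_precision,
)


def embed(pairs_ref, pairs_pred):
    """Place given masked values into 1 x n maps padded with 50 Å rows so
    only the intended pairs fall inside the (0, 36 Å) mask."""
    n = len(pairs_ref)
    ref = np.full((n + 1, n + 1), 50.0)
    pred = np.full((n + 1, n + 1), 50.0)
    for k, (r, p) in enumerate(zip(pairs_ref, pairs_pred)):
        ref[0, k + 1] = r
        pred[0, k + 1] = p
    return pred, ref


class TestDistanceMetrics:
    def test_hand_worked_three_pair_example(self):
        pred, ref = embed([4, 10, 20], [6, 10, 16])
        m = distance_metrics(pred, ref)
        assert m.mae_d == pytest.approx(2.0)
        assert m.rmse == pytest.approx(math.sqrt(20 / 3), abs=1e-3)
        assert m.r2 == pytest.approx(1 - 20 / (392 / 3), abs=1e-4)
        assert m.n_pairs == 3

    def test_perfect_prediction(self):
        rng = np.random.default_rng(0)
        ref = rng.random((6, 6)) * 30 + 1
        m = distance_metrics(ref, ref)
        assert (m.mae_d, m.rmse, m.r2) == (0.0, 0.0, 1.0)

    def test_constant_mean_prediction_has_zero_r2(self):
        pred, ref = embed([4, 10, 22], [12, 12, 12])
        assert distance_metrics(pred, ref).r2 == pytest.approx(0.0)

    def test_rmse_at_least_mae(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            ref = rng.random((8, 8)) * 34 + 1
            pred = ref + rng.normal(scale=3, size=ref.shape)
            m = distance_metrics(pred, ref)
            assert m.rmse >= m.mae_d

    def test_error_head_mae(self):
        pred, ref = embed([4, 10], [6, 13])       # realized AE = 2, 3
        err = np.zeros_like(pred)
        err[0, 1], err[0, 2] = 2.5, 2.0           # predicted AE
        m = distance_metrics(pred, ref, pred_err=err)
        assert m.mae_p == pytest.approx((0.5 + 1.0) / 2)

    def test_empty_mask_names_protein(self):
        far = np.full((3, 3), 60.0)
        with pytest.raises(ValueError, match="prot_x"):
            distance_metrics(far, far, protein_id="prot_x")


class TestDatasetSummary:
    def _metric(self, mae):
        pred, ref = embed([10.0, 20.0], [10.0 + mae, 20.0 + mae])
        return distance_metrics(pred, ref)

    def test_identical_proteins_have_zero_deviation(self):
        s = dataset_summary([self._metric(2), self._metric(2)])
        assert s.deviation["mae_d"] == 0.0

    def test_two_and_four_give_mean_three_deviation_one(self):
        s = dataset_summary([self._metric(2), self._metric(4)])
        assert s.mean["mae_d"] == pytest.approx(3.0)
        assert s.deviation["mae_d"] == pytest.approx(1.0)

    def test_single_protein_deviation_is_zero(self):
        s = dataset_summary([self._metric(1.5)])
        assert s.deviation["mae_d"] == 0.0


class TestContacts:
    def test_threshold_is_strict(self):
        cm = contact_from_distance(np.array([[0.0, 7.99], [8.0, 0.0]]))
        assert cm.contacts[0, 1] and not cm.contacts[1, 0]

    def test_far_map_has_no_contacts(self):
        cm = contact_from_distance(np.full((5, 5), 50.0))
        assert not cm.contacts[np.triu_indices(5, 1)].any()

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(2)
        d = rng.random((6, 6)) * 16
        cm = contact_from_distance(d)
        for i in range(6):
            for j in range(6):
                assert cm.contacts[i, j] == (d[i, j] < 8.0)


def exhaustive_topk(score, contacts, L, k_divisor, range_class):
    lo, hi = SEPARATION_CLASSES[range_class]
    pairs = [(i, j) for i in range(L) for j in range(i + 1, L)
             if j - i >= lo and (hi is None or j - i < hi)]
    if not pairs:
        return float("nan")
    pairs.sort(key=lambda p: (-score[p], p[0], p[1]))
    k = min(math.ceil(L / k_divisor), len(pairs))
    top = pairs[:k]
    return 100.0 * sum(contacts[p] for p in top) / k


class TestTopK:
    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(3)
        for trial in range(200):
            L = 8
            d = rng.random((L, L)) * 20
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0)
            score = -d + rng.normal(scale=2, size=d.shape)
            score = (score + score.T) / 2
            cm = contact_from_distance(d)
            for rc in ("all", "short"):
                got = topk_precision(score, cm, 5, rc)
                want = exhaustive_topk(score, cm.contacts, L, 5, rc)
                assert got == pytest.approx(want), (trial, rc)

    def test_perfect_scores_give_full_precision(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(scale=3.0, size=(30, 3))  # compact globule
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        cm = contact_from_distance(d)
        # enough genuine long-range contacts for the top-L/5 list
        i, j = np.triu_indices(30, k=24)
        assert cm.contacts[i, j].sum() >= math.ceil(30 / 5)
        assert topk_precision(-d, cm, 5, "long") == 100.0

    def test_empty_class_reports_missing(self):
        d = np.full((8, 8), 50.0)
        np.fill_diagonal(d, 0)
        assert math.isnan(topk_precision(-d, contact_from_distance(d), 5,
                                         "long"))

    def test_short_candidate_list_warns_and_uses_all(self):
        d = np.random.default_rng(5).random((7, 7)) * 30
        cm = contact_from_distance(d)
        with pytest.warns(UserWarning, match="using all"):
            topk_precision(-d, cm, 1, "short")


class TestClassifierMetrics:
    def _instance(self, seed=6, L=24):
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(scale=1.8, size=(L, 3)), axis=0)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        return d, contact_from_distance(d)

    def test_perfectly_separating_scores(self):
        d, cm = self._instance()
        out = classifier_metrics(-d, cm)
        assert out["auroc"] == pytest.approx(1.0)
        assert out["aupr"] == pytest.approx(1.0, abs=1e-9)
        assert out["f1"] == pytest.approx(1.0)

    def test_random_scores_near_half_auroc(self):
        d, cm = self._instance(L=40)
        rng = np.random.default_rng(7)
        aurocs = [classifier_metrics(rng.normal(size=d.shape), cm)["auroc"]
                  for _ in range(20)]
        assert abs(np.mean(aurocs) - 0.5) < 0.1

    def test_auroc_invariant_under_monotone_transform(self):
        d, cm = self._instance(seed=8)
        rng = np.random.default_rng(9)
        score = -d + rng.normal(scale=3, size=d.shape)
        base = classifier_metrics(score, cm)["auroc"]
        for f in (lambda s: 3 * s + 7, np.tanh, lambda s: s ** 3):
            assert classifier_metrics(f(score), cm)["auroc"] == \
                pytest.approx(base)

    def test_four_pair_toy_matches_rank_sum(self):
        """AUROC equals the normalized Mann-Whitney U statistic."""
        ref = np.full((9, 9), 50.0)
        ref[0, 6], ref[0, 7] = 5.0, 5.0      # contacts
        ref[0, 8], ref[1, 7] = 20.0, 20.0    # non-contacts
        cm = contact_from_distance(ref)
        score = np.zeros((9, 9))
        score[0, 6], score[0, 7], score[0, 8], score[1, 7] = 4.0, 2.0, 3.0, 1.0
        i, j = np.triu_indices(9, k=6)
        y = cm.contacts[i, j]
        s = score[i, j]
        pos, neg = s[y], s[~y]
        u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        expected = u / (len(pos) * len(neg))
        assert classifier_metrics(score, cm)["auroc"] == pytest.approx(expected)

    def test_single_class_rejected(self):
        d = np.full((10, 10), 50.0)
        with pytest.raises(ValueError, match="both contact and non-contact"):
            classifier_metrics(-d, contact_from_distance(d))


class TestChannelCorrelation:
    def test_exact_positive_and_negative_correlation(self):
        rng = np.random.default_rng(10)
        ref = rng.random((7, 7)) * 30 + 1
        pooled = np.stack([ref, -ref + 40.0])
        r = channel_correlation(pooled, ref)
        assert r[0] == pytest.approx(1.0)
        assert r[1] == pytest.approx(-1.0)

    def test_matches_loop_oracle_on_random_channel(self):
        rng = np.random.default_rng(11)
        ref = rng.random((6, 6)) * 30 + 1
        chan = rng.random((1, 6, 6))
        mask = (ref > 0) & (ref < 36)
        x, d = chan[0][mask], ref[mask]
        num = ((x - x.mean()) * (d - d.mean())).sum()
        den = np.sqrt(((x - x.mean()) ** 2).sum() * ((d - d.mean()) ** 2).sum())
        assert channel_correlation(chan, ref)[0] == pytest.approx(num / den)
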