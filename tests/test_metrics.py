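"""Quality coefficients against brute-force from-definition oracles."""

import numpy as np
import pytest

from oostage import aggregate, detection_ratio, iou, per_class_metrics, tally_from_predictions
from oostage.metrics import ConfusionTally
from oostage.records import LABELS


def _random_tally(rng, n=30):
    truth = rng.choice(LABELS, size=n)
    pred = rng.choice(LABELS, size=n)
    return truth, pred, tally_from_predictions(truth, pred)


class TestTally:
    def test_all_correct(self):
        labels = ["MI"] * 3 + ["MII"] * 3 + ["PI"] * 3
        t = tally_from_predictions(labels, labels)
        for c in LABELS:
            assert t.counts[c] == {"Tp": 3, "Fp": 0, "Fn": 0, "Tn": 6}

    def test_all_predicted_mii(self):
        truth = ["MI"] * 4 + ["MII"] * 5 + ["PI"] * 2
        t = tally_from_predictions(truth, ["MII"] * 11)
        assert t.counts["MII"]["Tp"] == 5
        assert t.counts["MI"]["Fn"] == 4
        assert t.counts["MII"]["Fp"] == 6

    def test_matches_counting_oracle(self, rng):
        for _ in range(200):
            truth, pred, t = _random_tally(rng)
            for c in LABELS:
                tp = sum(x == c and y == c for x, y in zip(truth, pred))
                fp = sum(x != c and y == c for x, y in zip(truth, pred))
                fn = sum(x == c and y != c for x, y in zip(truth, pred))
                tn = sum(x != c and y != c for x, y in zip(truth, pred))
                assert t.counts[c] == {"Tp": tp, "Fp": fp, "Fn": fn, "Tn": tn}

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            tally_from_predictions(["MI"], ["degenerated"])


class TestPerClassMetrics:
    def test_perfect_tally(self):
        t = ConfusionTally({c: {"Tp": 3, "Fp": 0, "Fn": 0, "Tn": 6} for c in LABELS})
        df = per_class_metrics(t)
        for c in LABELS:
            assert df.loc[c, ["ACC", "TPR", "PPV", "f1"]].tolist() == [1, 1, 1, 1]
            assert df.loc[c, "FDR"] == 0

    def test_direct_substitution(self):
        t = ConfusionTally({c: {"Tp": 0, "Fp": 2, "Fn": 1, "Tn": 6} for c in LABELS})
        row = per_class_metrics(t).loc["MI"]
        assert row["TPR"] == 0 and row["PPV"] == 0 and row["FDR"] == 1
        assert row["ACC"] == pytest.approx(6 / 9)

    def test_matches_formula_oracle_on_random_tallies(self, rng):
        """1000 random tallies agree with naive formula evaluation to 1e-12."""
        for _ in range(1000):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 20, size=4))
            t = ConfusionTally({c: {"Tp": tp, "Fp": fp, "Fn": fn, "Tn": tn} for c in LABELS})
            row = per_class_metrics(t).loc["MII"]
            tpr = tp / (tp + fn) if tp + fn else 0.0
            ppv = tp / (tp + fp) if tp + fp else 0.0
            fdr = fp / (fp + tp) if fp + tp else 0.0
            acc = (tp + tn) / (tp + tn + fp + fn) if tp + tn + fp + fn else 0.0
            f1 = 2 * ppv * tpr / (ppv + tpr) if ppv + tpr else 0.0
            for name, want in (("TPR", tpr), ("PPV", ppv), ("FDR", fdr), ("ACC", acc), ("f1", f1)):
                assert row[name] == pytest.approx(want, abs=1e-12)

    def test_ppv_plus_fdr_identity(self, rng):
        for _ in range(200):
            _, _, t = _random_tally(rng)
            df = per_class_metrics(t)
            for c in LABELS:
                if t.counts[c]["Tp"] + t.counts[c]["Fp"] > 0:
                    assert df.loc[c, "PPV"] + df.loc[c, "FDR"] == pytest.approx(1.0, abs=1e-12)

    def test_as_printed_convention(self):
        t = ConfusionTally({c: {"Tp": 3, "Fp": 1, "Fn": 2, "Tn": 4} for c in LABELS})
        assert per_class_metrics(t, "as-printed").loc["MI", "ACC"] == pytest.approx(3 / 7)


class TestIoU:
    def test_identical_and_disjoint(self):
        a = np.zeros((10, 10), np.uint8); a[:3, :3] = 1
        b = np.zeros((10, 10), np.uint8); b[5:, 5:] = 1
        assert iou(a, a) == 1.0
        assert iou(a, b) == 0.0

    def test_both_empty_convention(self):
        z = np.zeros((5, 5), np.uint8)
        assert iou(z, z) == 1.0

    def test_matches_set_oracle(self, rng):
        for _ in range(1000):
            a = rng.uniform(size=(8, 8)) < 0.4
            b = rng.uniform(size=(8, 8)) < 0.4
            sa = {t for t in zip(*np.nonzero(a))}
            sb = {t for t in zip(*np.nonzero(b))}
            want = len(sa & sb) / len(sa | sb) if sa | sb else 1.0
            assert iou(a, b) == pytest.approx(want, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            iou(np.zeros((3, 3)), np.zeros((4, 4)))


class TestAggregate:
    def _tally(self, rng, srrs_id):
        truth = rng.choice(LABELS, size=20)
        pred = rng.choice(LABELS, size=20)
        t = tally_from_predictions(truth, pred, srrs_id=srrs_id)
        return t

    def test_identical_values_passthrough(self):
        t = ConfusionTally({c: {"Tp": 3, "Fp": 0, "Fn": 0, "Tn": 6} for c in LABELS})
        rep = aggregate([t, t, t])
        assert rep.means["ACC"] == 1.0 and rep.means["TPR"] == 1.0

    def test_repetition_mean_is_class_mean(self):
        # per-class ACC 1.0 / 0.5 / 0.0 within one repetition -> mean 0.5
        counts = {
            "MI": {"Tp": 5, "Fp": 0, "Fn": 0, "Tn": 5},   # ACC 1.0
            "MII": {"Tp": 2, "Fp": 2, "Fn": 3, "Tn": 3},  # ACC 0.5
            "PI": {"Tp": 0, "Fp": 5, "Fn": 5, "Tn": 0},   # ACC 0.0
        }
        rep = aggregate([ConfusionTally(counts)])
        assert rep.per_repetition.loc[0, "ACC"] == pytest.approx(0.5)

    def test_matches_nested_mean_oracle(self, rng):
        """Nested SRRS means equal naive class-then-repetition averaging."""
        for _ in range(100):
            tallies = [self._tally(rng, k) for k in range(3)]
            rep = aggregate(tallies)
            per_rep = []
            for t in tallies:
                df = per_class_metrics(t)
                per_rep.append(np.mean([df.loc[c, "ACC"] for c in LABELS]))
            assert rep.means["ACC"] == pytest.approx(np.mean(per_rep), abs=1e-12)

    def test_missing_class_rejected(self):
        t = ConfusionTally({"MI": {"Tp": 1, "Fp": 0, "Fn": 0, "Tn": 0}})
        with pytest.raises(ValueError, match="MII"):
            aggregate([t])

    def test_values_within_unit_interval(self, rng):
        rep = aggregate([self._tally(rng, k) for k in range(5)])
        assert all(0 <= v <= 1 for v in rep.means.values())


class TestDetectionRatio:
    @pytest.mark.parametrize("outcomes,want", [([True] * 4, 1.0), ([False] * 4, 0.0),
                                               ([True] * 7 + [False] * 3, 0.7)])
    def test_ratios(self, outcomes, want):
        assert detection_ratio(outcomes) == want

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            detection_ratio([])
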