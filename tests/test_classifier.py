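"""Architecture building, analytic FLOPs, training/selection/inference."""

import numpy as np
import pytest

from oostage import (ChannelSelection, TensorDataset, TrainConfig, build_architecture, classify,
                     count_flops, select_snapshot, train_classifier)
from oostage.classifier import Chromosome, REFERENCE_CHROMOSOME, Snapshot, load_snapshot, save_snapshot
from oostage.dataio import InputTensor
from oostage.records import FPB, GV
from oostage.sampling import SrrsPlan, srrs_split

REFERENCE = REFERENCE_CHROMOSOME  # (32, 16, 8, 28, 28, 4)


def _shape_oracle(side, kernel, stride, padding):
    return (side + 2 * padding - kernel) // stride + 1


class TestChromosome:
    def test_bounds_and_parity_enforced(self):
        Chromosome((2, 128, 64, 2, 2, 2))
        with pytest.raises(ValueError):
            Chromosome((3, 4, 4, 4, 4, 4))
        with pytest.raises(ValueError):
            Chromosome((130, 4, 4, 4, 4, 4))
        with pytest.raises(ValueError):
            Chromosome((4, 4, 4, 4, 4))


class TestBuildArchitecture:
    def test_reference_first_conv_activation(self):
        """At 590x590x2 the stride-2 3x3 stem yields a 294x294x32 activation."""
        spec = build_architecture(REFERENCE, 2, 1, 590)
        assert spec.layer("conv1").out_shape == (32, 294, 294)

    def test_reference_filter_column(self):
        spec = build_architecture(REFERENCE, 2, 1, 590)
        for name, want in [("conv1", 32), ("conv2", 16), ("squeeze1", 8),
                           ("fire1_3x3", 28), ("fire1_1x1", 28), ("conv6", 4), ("conv7", 4)]:
            assert spec.layer(name).filters == want
        assert spec.layer("concat1").out_shape[0] == 56
        assert spec.layer("fc").out_shape == (3,)

    def test_zero_blocks_has_no_concat(self):
        spec = build_architecture(REFERENCE, 2, 0, 128)
        assert not any(s.kind == "concat" for s in spec.layers)

    def test_shape_propagation_matches_hand_calculation(self, rng):
        """Spatial sizes agree with the closed-form conv/pool arithmetic."""
        for _ in range(20):
            genes = tuple(int(2 * rng.integers(1, 65)) for _ in range(6))
            side = int(rng.choice([96, 128, 160]))
            blocks = int(rng.integers(0, 3))
            spec = build_architecture(genes, 2, blocks, side)
            s = _shape_oracle(side, 3, 2, 0)          # conv1
            assert spec.layer("conv1").out_shape[1] == s
            s = _shape_oracle(s, 3, 2, 0)             # pool1
            s = _shape_oracle(s, 3, 2, 0)             # pool2 (conv2 is 1x1)
            for b in range(1, blocks + 1):
                assert spec.layer(f"concat{b}").out_shape[1:] == (s, s)
                s = _shape_oracle(s, 3, 2, 0)         # block pool
            assert spec.layer("conv7").out_shape == (genes[5], s, s)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            build_architecture(REFERENCE, 2, 5, 590)
        with pytest.raises(ValueError):
            build_architecture((4, 4, 4, 4, 4, 4, 4), 2, 1, 590)


class TestCountFlops:
    def test_single_1x1_conv_unit(self):
        from oostage._net import LayerSpec, propagate_shapes
        from oostage.classifier import ArchitectureSpec

        layers = propagate_shapes(
            [LayerSpec("input", "input"), LayerSpec("c", "conv", ("input",), kernel=1, filters=1)],
            (1, 1, 1),
        )
        spec = ArchitectureSpec(tuple(layers), Chromosome((2, 2, 2, 2, 2, 2)), 1, 0, 1)
        assert count_flops(spec) == 1
        assert count_flops(spec, mac=2) == 2

    @pytest.mark.parametrize(
        "genes,blocks,side",
        [
            (REFERENCE, 1, 590),
            ((2, 2, 2, 2, 2, 2), 0, 96),
            ((8, 8, 8, 8, 8, 4), 1, 136),
            ((16, 4, 4, 12, 12, 8), 2, 160),
            ((64, 32, 16, 56, 56, 8), 1, 256),
        ],
    )
    def test_matches_spreadsheet_oracle(self, genes, blocks, side):
        """Layer-by-layer independent MAC count reproduces count_flops."""
        spec = build_architecture(genes, 2, blocks, side)
        shapes = {s.name: s.out_shape for s in spec.layers}
        total = 0
        for s in spec.layers:
            if s.kind == "conv":
                cin = shapes[s.inputs[0]][0]
                c, h, w = s.out_shape
                total += h * w * c * s.kernel**2 * cin
            elif s.kind == "fc":
                total += int(np.prod(shapes[s.inputs[0]])) * s.filters
        assert count_flops(spec) == total

    def test_monotone_in_filters(self):
        base = count_flops(build_architecture((8, 8, 8, 8, 8, 4), 2, 1, 136))
        for i in range(6):
            genes = list((8, 8, 8, 8, 8, 4))
            genes[i] *= 2
            assert count_flops(build_architecture(tuple(genes), 2, 1, 136)) >= base

    def test_monotone_in_input_side(self):
        f = [count_flops(build_architecture(REFERENCE, 2, 1, s)) for s in (128, 256, 590)]
        assert f[0] < f[1] < f[2]

    def test_fewer_blocks_fewer_flops(self):
        f = [count_flops(build_architecture(REFERENCE, 2, b, 590)) for b in (0, 1, 2, 3, 4)]
        assert all(a < b for a, b in zip(f, f[1:]))

    def test_reference_flops_order_of_magnitude(self):
        """The 2-channel reference structure lands in the 1e8 FLOPs decade."""
        flops = count_flops(build_architecture(REFERENCE, 2, 1, 590))
        assert 1e7 < flops < 1e9


@pytest.fixture(scope="module")
def trained(small_dataset):
    records = small_dataset[0]
    ds = TensorDataset.from_records(records, ChannelSelection((FPB, GV), merge_fpb=True), side=96)
    ids_by_class = {}
    for r in records:
        ids_by_class.setdefault(r.label, []).append(r.id)
    plan = SrrsPlan(repetitions=1, validation={"MI": 3, "MII": 3, "PI": 3},
                    test={"MI": 2, "MII": 2, "PI": 2}, seed=0)
    rep = srrs_split(ids_by_class, plan)[0]
    arch = build_architecture((8, 8, 8, 8, 8, 4), 2, 1, 96)
    cfg = TrainConfig(epochs=10, batch_size=30, steps_per_epoch=4, learning_rate=2e-2, seed=0)
    snaps = train_classifier(ds, rep, arch, cfg)
    return ds, rep, snaps


class TestTraining:
    def test_one_snapshot_per_epoch_with_finite_loss(self, trained):
        _, _, snaps = trained
        assert len(snaps) == 10
        assert all(np.isfinite(s.metrics["train_loss"]) for s in snaps)

    def test_loss_decreases_on_separable_task(self, trained):
        _, _, snaps = trained
        assert snaps[-1].metrics["train_loss"] < snaps[0].metrics["train_loss"]

    def test_validation_accuracy_reaches_mask_separable_ceiling(self, trained):
        _, _, snaps = trained
        assert select_snapshot(snaps).metrics["val_accuracy"] >= 0.95

    def test_missing_record_rejected(self, trained):
        ds, rep, snaps = trained
        bad = dict(rep, train=rep["train"] + ["ghost"])
        with pytest.raises(ValueError, match="ghost"):
            train_classifier(ds, bad, snaps[0].arch, TrainConfig(epochs=1))


class TestSelectSnapshot:
    def _snap(self, epoch, acc):
        return Snapshot(epoch=epoch, state={}, metrics={"val_accuracy": acc}, arch=None)

    def test_argmax(self):
        snaps = [self._snap(i + 1, a) for i, a in enumerate([0.5, 0.9, 0.8])]
        assert select_snapshot(snaps).epoch == 2

    def test_tie_takes_earliest(self):
        snaps = [self._snap(i + 1, 0.7) for i in range(3)]
        assert select_snapshot(snaps).epoch == 1

    def test_matches_argmax_oracle(self, rng):
        for _ in range(1000):
            accs = rng.uniform(size=rng.integers(1, 8))
            snaps = [self._snap(i + 1, a) for i, a in enumerate(accs)]
            assert select_snapshot(snaps).epoch == int(np.argmax(accs)) + 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_snapshot([])


class TestClassify:
    def test_probabilities_normalized_and_deterministic(self, trained):
        ds, rep, snaps = trained
        best = select_snapshot(snaps)
        t = ds.load(rep["test"][0], 0)
        label1, p1 = classify(t, best)
        label2, p2 = classify(t, best)
        assert p1.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(p1 >= 0)
        assert label1 == label2 and np.array_equal(p1, p2)

    def test_shape_mismatch_rejected(self, trained):
        _, _, snaps = trained
        bad = InputTensor(np.zeros((32, 32, 2), np.float32), (FPB, GV))
        with pytest.raises(ValueError, match="shape"):
            classify(bad, snaps[0])

    def test_snapshot_roundtrip(self, trained, tmp_path):
        ds, rep, snaps = trained
        best = select_snapshot(snaps)
        save_snapshot(best, tmp_path / "snap")
        loaded = load_snapshot(tmp_path / "snap")
        t = ds.load(rep["val"][0], 0)
        assert classify(t, best)[1] == pytest.approx(classify(t, loaded)[1])
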