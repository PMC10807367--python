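import numpy as np
import pandas as pd
import pytest

from bscso.data import (
    LabeledDataset,
    SplitSpec,
    SyntheticSpec,
    generate_synthetic,
    load_table,
    normalize_minmax,
    split,
)
from bscso.fitness import test_accuracy as subset_test_accuracy

CSV_TEXT = "a,b,cls\n1,10,yes\n2,20,no\n3,30,yes\n4,40,no\n"

ARFF_TEXT = """@relation toy
@attribute a numeric
@attribute b numeric
@attribute cls {yes,no}
@data
1,10,yes
2,20,no
3,30,yes
4,40,no
"""


class TestLoadTable:
    def test_csv_shapes_and_encoding(self, tmp_path):
        p = tmp_path / "toy.csv"
        p.write_text(CSV_TEXT)
        ds = load_table(p)
        assert (ds.n_samples, ds.n_features, ds.n_classes) == (4, 2, 2)
        assert ds.feature_names == ["a", "b"]
        # labels encoded in first-appearance order
        np.testing.assert_array_equal(ds.labels, [0, 1, 0, 1])
        assert ds.class_names == ["yes", "no"]

    def test_arff_equivalent_to_csv(self, tmp_path):
        pc = tmp_path / "toy.csv"
        pa = tmp_path / "toy.arff"
        pc.write_text(CSV_TEXT)
        pa.write_text(ARFF_TEXT)
        a, b = load_table(pc), load_table(pa)
        np.testing.assert_array_equal(a.features, b.features)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.class_names == b.class_names

    def test_label_column_by_name(self, tmp_path):
        p = tmp_path / "toy.csv"
        p.write_text("cls,a,b\nyes,1,10\nno,2,20\n")
        ds = load_table(p, label_column="cls")
        assert ds.feature_names == ["a", "b"]

    def test_unparseable_cell_named(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b,cls\n1,10,yes\n2,oops,no\n")
        with pytest.raises(ValueError, match=r"row 1.*'b'"):
            load_table(p)

    def test_single_class_rejected(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("a,cls\n1,yes\n2,yes\n")
        with pytest.raises(ValueError, match="single class"):
            load_table(p)

    def test_missing_rows_dropped_and_counted(self, tmp_path):
        p = tmp_path / "holes.csv"
        p.write_text("a,b,cls\n1,10,yes\n2,,no\n3,30,yes\n4,40,no\n")
        ds = load_table(p)
        assert ds.n_samples == 3
        assert ds.n_dropped_rows == 1
        with pytest.raises(ValueError, match="missing"):
            load_table(p, on_missing="error")


class TestNormalize:
    def test_affine_rescale(self):
        ds = LabeledDataset(
            np.array([[0.0], [5.0], [10.0]]), [0, 1, 0], ["x"], 2
        )
        out = normalize_minmax(ds)
        np.testing.assert_allclose(out.features[:, 0], [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        ds = LabeledDataset(np.full((3, 1), 3.0), [0, 1, 0], ["x"], 2)
        np.testing.assert_array_equal(normalize_minmax(ds).features, 0.0)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        ds = LabeledDataset(
            rng.uniform(-5, 5, (20, 4)), rng.integers(0, 2, 20),
            [f"x{i}" for i in range(4)], 2,
        )
        once = normalize_minmax(ds)
        twice = normalize_minmax(once)
        np.testing.assert_allclose(once.features, twice.features, atol=1e-15)
        assert once.features.min() >= 0 and once.features.max() <= 1

    def test_reference_parameters_from_training_partition(self):
        tr = LabeledDataset(np.array([[0.0], [10.0]]), [0, 1], ["x"], 2)
        te = LabeledDataset(np.array([[5.0], [20.0]]), [0, 1], ["x"], 2)
        out = normalize_minmax(te, reference=tr)
        np.testing.assert_allclose(out.features[:, 0], [0.5, 2.0])


class TestSplit:
    def _dataset(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return LabeledDataset(
            rng.uniform(size=(n, 3)),
            np.arange(n) % 2,
            ["a", "b", "c"],
            2,
        )

    def test_three_way_sizes(self):
        tr, va, te = split(self._dataset(), SplitSpec(seed=1))
        assert (tr.n_samples, va.n_samples, te.n_samples) == (60, 20, 20)

    def test_two_way_protocol(self):
        tr, va, te = split(
            self._dataset(),
            SplitSpec(train_fraction=0.8, validation_fraction=0.0,
                      test_fraction=0.2, seed=1),
        )
        assert (tr.n_samples, va.n_samples, te.n_samples) == (80, 0, 20)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("fracs", [(0.6, 0.2, 0.2), (0.5, 0.25, 0.25)])
    def test_partitions_disjoint_and_exhaustive(self, seed, fracs):
        ds = self._dataset()
        # tag rows through a unique feature value to track assignment
        ds.features[:, 0] = np.arange(100)
        tr, va, te = split(
            ds, SplitSpec(*fracs, stratified=True, seed=seed)
        )
        ids = np.concatenate(
            [tr.features[:, 0], va.features[:, 0], te.features[:, 0]]
        )
        assert sorted(ids.tolist()) == list(range(100))

    def test_stratified_proportions(self):
        rng = np.random.default_rng(5)
        ds = LabeledDataset(
            rng.uniform(size=(100, 2)),
            np.repeat([0, 1, 2], [50, 30, 20]),
            ["a", "b"],
            3,
        )
        tr, va, te = split(ds, SplitSpec(seed=2))
        for part, frac in ((tr, 0.6), (va, 0.2), (te, 0.2)):
            counts = np.bincount(part.labels, minlength=3)
            expected = np.array([50, 30, 20]) * frac
            assert np.all(np.abs(counts - expected) <= 1)

    def test_deterministic(self):
        ds = self._dataset()
        ds.features[:, 0] = np.arange(100)
        a = split(ds, SplitSpec(seed=9))
        b = split(ds, SplitSpec(seed=9))
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.features, y.features)

    def test_tiny_class_fails_stratification(self):
        ds = LabeledDataset(
            np.zeros((10, 1)), [0] * 9 + [1], ["a"], 2
        )
        with pytest.raises(ValueError, match="stratified"):
            split(ds, SplitSpec(seed=0))

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            SplitSpec(0.5, 0.2, 0.2)


class TestSynthetic:
    def test_construction_contract(self):
        synth = generate_synthetic(
            SyntheticSpec(n_samples=100, n_features=20, n_informative=5,
                          effect_size=3.0, seed=1)
        )
        ds = synth.dataset
        assert ds.features.shape == (100, 20)
        assert np.bincount(ds.labels).tolist() == [50, 50]
        assert synth.informative_indices.shape == (5,)

    def test_mean_separation_on_informative_and_noise_features(self):
        synth = generate_synthetic(
            SyntheticSpec(n_samples=100, n_features=20, n_informative=5,
                          effect_size=3.0, seed=7)
        )
        ds = synth.dataset
        diff = (
            ds.features[ds.labels == 1].mean(axis=0)
            - ds.features[ds.labels == 0].mean(axis=0)
        )
        informative = np.zeros(20, dtype=bool)
        informative[synth.informative_indices] = True
        assert np.all(np.abs(diff[informative] - 3.0) < 0.6)
        assert np.all(np.abs(diff[~informative]) < 0.6)

    def test_deterministic(self):
        spec = SyntheticSpec(seed=3)
        a, b = generate_synthetic(spec), generate_synthetic(spec)
        np.testing.assert_array_equal(a.dataset.features, b.dataset.features)
        np.testing.assert_array_equal(a.informative_indices, b.informative_indices)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_features=5, n_informative=6)
        with pytest.raises(ValueError):
            SyntheticSpec(n_samples=6, n_classes=2)

    def test_no_signal_data_gives_chance_accuracy(self):
        """With zero effect size every subset classifies at chance level."""
        accs = []
        for seed in range(20):
            synth = generate_synthetic(
                SyntheticSpec(n_samples=100, n_features=10, n_informative=5,
                              effect_size=0.0, seed=seed)
            )
            tr, _va, te = split(synth.dataset, SplitSpec(seed=seed))
            bits = np.zeros(10, dtype=np.int8)
            bits[seed % 10] = 1
            bits[(seed + 3) % 10] = 1
            accs.append(
                subset_test_accuracy(
                    tr.features, tr.labels, te.features, te.labels, bits, k=5
                )
            )
        accs = np.array(accs)
        se = accs.std(ddof=1) / np.sqrt(len(accs))
        assert abs(accs.mean() - 0.5) <= 3 * se + 1e-9
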