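import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sigcpc.data import EpochDataset, SynthConfig, generate_dataset
from sigcpc.pairs import (
    BLOCK_SIZE,
    PairSamplingError,
    SamplePair,
    build_negative_pair,
    build_positive_pair,
    pair_batch,
)


def check_pair_invariants(pair: SamplePair, dataset: EpochDataset) -> None:
    assert pair.left_block.shape[0] == BLOCK_SIZE
    assert pair.right_block.shape[0] == BLOCK_SIZE
    assert np.all(dataset.labels[pair.left_indices] == pair.left_class)
    assert np.all(dataset.labels[pair.right_indices] == pair.right_class)
    all_idx = np.concatenate([pair.left_indices, pair.right_indices])
    if pair.pair_label == 1:
        assert pair.left_class == pair.right_class
        assert len(set(all_idx)) == 2 * BLOCK_SIZE  # 8 distinct epochs
    else:
        assert pair.left_class != pair.right_class
        assert len(set(pair.left_indices)) == BLOCK_SIZE
        assert len(set(pair.right_indices)) == BLOCK_SIZE


class TestPositivePair:
    def test_same_class_and_label(self, small_dataset):
        rng = np.random.default_rng(0)
        pair = build_positive_pair(small_dataset, 2, rng)
        assert pair.pair_label == 1
        check_pair_invariants(pair, small_dataset)

    def test_exactly_eight_members_forces_them_all(self):
        ds = EpochDataset(np.arange(16 * 8, dtype=float).reshape(16, 8),
                          [0] * 8 + [1] * 8)
        pair = build_positive_pair(ds, 0, np.random.default_rng(1))
        assert sorted(np.concatenate([pair.left_indices, pair.right_indices])) == list(range(8))

    def test_too_few_members_raises(self):
        ds = EpochDataset(np.zeros((10, 8)), [0] * 7 + [1] * 3)
        with pytest.raises(PairSamplingError, match="class 0"):
            build_positive_pair(ds, 0, np.random.default_rng(0))

    def test_draws_are_uniform_over_members(self):
        """Chi-square check: each eligible epoch should be drawn equally often."""
        ds = EpochDataset(np.zeros((12, 8)), [0] * 12)
        rng = np.random.default_rng(2)
        counts = np.zeros(12)
        n_draws = 4000
        for _ in range(n_draws):
            pair = build_positive_pair(ds, 0, rng)
            counts[np.concatenate([pair.left_indices, pair.right_indices])] += 1
        expected = n_draws * 8 / 12
        # scale chi-square by the within-draw dependence factor (8 draws w/o replacement)
        chi2 = ((counts - expected) ** 2 / expected).sum() / (1 - 8 / 12)
        assert stats.chi2.sf(chi2, df=11) > 1e-4


class TestNegativePair:
    def test_distinct_classes_and_label(self, small_dataset):
        pair = build_negative_pair(small_dataset, 0, 2, np.random.default_rng(3))
        assert pair.pair_label == 0
        assert (pair.left_class, pair.right_class) == (0, 2)
        check_pair_invariants(pair, small_dataset)

    def test_equal_classes_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="distinct"):
            build_negative_pair(small_dataset, 1, 1, np.random.default_rng(0))

    def test_insufficient_epochs_raises(self):
        ds = EpochDataset(np.zeros((10, 8)), [0] * 8 + [1] * 2)
        with pytest.raises(PairSamplingError, match="class 1"):
            build_negative_pair(ds, 0, 1, np.random.default_rng(0))


class TestPairBatch:
    def test_composition_and_shuffle(self, small_dataset):
        batch = pair_batch(small_dataset, 32, 0.5, np.random.default_rng(4))
        labels = [p.pair_label for p in batch]
        assert len(batch) == 32
        assert sum(labels) == 16  # exact positive count after rounding
        for p in batch:
            check_pair_invariants(p, small_dataset)

    @pytest.mark.parametrize("frac,expected", [(0.25, 8), (0.0, 0), (1.0, 32)])
    def test_positive_fraction_rounding(self, small_dataset, frac, expected):
        batch = pair_batch(small_dataset, 32, frac, np.random.default_rng(5))
        assert sum(p.pair_label for p in batch) == expected

    def test_deterministic_under_seed(self, small_dataset):
        a = pair_batch(small_dataset, 8, 0.5, np.random.default_rng(6))
        b = pair_batch(small_dataset, 8, 0.5, np.random.default_rng(6))
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.left_indices, pb.left_indices)
            assert np.array_equal(pa.right_indices, pb.right_indices)
            assert pa.pair_label == pb.pair_label

    def test_negative_class_pairs_near_uniform(self, small_dataset):
        """All ordered unequal (left, right) class pairs occur at comparable
        frequency across many negative draws."""
        rng = np.random.default_rng(7)
        counts = {}
        n = 6000
        for _ in range(n):
            for p in pair_batch(small_dataset, 2, 0.0, rng):
                counts[(p.left_class, p.right_class)] = counts.get(
                    (p.left_class, p.right_class), 0
                ) + 1
        assert len(counts) == 6  # 3 classes -> 6 ordered unequal pairs
        observed = np.array(list(counts.values()))
        chi2, p_value = stats.chisquare(observed)
        assert p_value > 1e-4

    def test_constructor_rejects_inconsistent_pairs(self, small_dataset):
        with pytest.raises(ValueError, match="positive"):
            SamplePair(
                left_block=np.zeros((4, 8)), right_block=np.zeros((4, 8)),
                pair_label=1, left_class=0, right_class=1,
                left_indices=np.arange(4), right_indices=np.arange(4, 8),
            )


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    n_classes=st.integers(2, 5),
    n_per_class=st.integers(8, 15),
    batch_size=st.integers(2, 12),
    seed=st.integers(0, 10_000),
)
def test_pair_invariants_hold_on_random_datasets(n_classes, n_per_class, batch_size, seed):
    freqs = tuple(2.0 + 3.0 * k for k in range(n_classes))
    ds = generate_dataset(
        SynthConfig(
            n_classes=n_classes, n_per_class=n_per_class, epoch_length=16,
            class_freqs=freqs, class_amps=(1.0,) * n_classes,
            noise_sd=0.1, seed=seed,
        )
    )
    for pair in pair_batch(ds, batch_size, 0.5, np.random.default_rng(seed)):
        check_pair_invariants(pair, ds)
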