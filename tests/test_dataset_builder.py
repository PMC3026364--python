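import numpy as np
import pytest

from siddprom import (
    DatasetConfig,
    SiddProfile,
    TssRecord,
    build_dataset,
    extract_window,
    sample_negatives,
    split_dataset,
)
from siddprom.dataset_builder import (
    LabeledDataset,
    average_profile_around_tss,
    eligible_negative_starts,
)
from siddprom.errors import SamplingError, WindowOutOfRangeError
from siddprom.sidd_io import NON_PROMOTER, PROMOTER, window_indices
from conftest import make_window


def position_profile(length, topology="linear"):
    """Profile whose value at 1-based position p is p itself."""
    return SiddProfile(np.arange(1, length + 1, dtype=float), topology=topology)


class TestExtractWindow:
    def test_forward_linear_covers_800_to_1049(self):
        profile = position_profile(2000)
        window = extract_window(profile, TssRecord("t", 1000, "forward"))
        expected = list(range(800, 1000)) + list(range(1000, 1050))
        assert window.energies.tolist() == [float(p) for p in expected]
        assert window.origin == 1000 and window.label == PROMOTER

    def test_reverse_linear_reads_against_the_genome(self):
        profile = position_profile(2000)
        window = extract_window(profile, TssRecord("t", 1000, "reverse"))
        expected = list(range(1200, 1000, -1)) + list(range(1000, 950, -1))
        assert window.energies.tolist() == [float(p) for p in expected]

    def test_circular_wraps_with_modular_arithmetic(self):
        profile = position_profile(1000, topology="circular")
        window = extract_window(profile, TssRecord("t", 100, "forward"))
        # independent modular-arithmetic oracle over relative positions
        expected = []
        for r in list(range(-200, 0)) + list(range(1, 51)):
            pos = 100 + r if r < 0 else 100 + r - 1
            expected.append(float((pos - 1) % 1000 + 1))
        assert window.energies.tolist() == expected
        assert 900.0 in window.energies and 999.0 in window.energies

    @pytest.mark.parametrize("position,strand", [(100, "forward"), (1960, "forward"), (30, "reverse")])
    def test_linear_out_of_range_raises(self, position, strand):
        profile = position_profile(2000)
        with pytest.raises(WindowOutOfRangeError):
            extract_window(profile, TssRecord("t", position, strand))

    @pytest.mark.parametrize("position", [300, 999, 1700])
    @pytest.mark.parametrize("strand", ["forward", "reverse"])
    def test_always_exactly_250_energies(self, position, strand):
        profile = position_profile(2000)
        window = extract_window(profile, TssRecord("t", position, strand))
        assert window.energies.size == 250


def window_genome_positions(inst, length, topology):
    """1-based genome positions a window covers (independent of builder)."""
    rel = np.concatenate([np.arange(-200, 0), np.arange(1, 51)])
    return window_indices(inst.origin, inst.strand, rel, length, topology) + 1


class TestSampleNegatives:
    def test_exhaustive_distance_check(self):
        profile = position_profile(10_000)
        tss = [TssRecord("t", 5000, "forward")]
        cfg = DatasetConfig(exclusion_radius=250, neg_pos_ratio=3, seed=2)
        negatives = sample_negatives(profile, tss, cfg)
        assert len(negatives) == 3
        for inst in negatives:
            assert inst.label == NON_PROMOTER
            positions = window_genome_positions(inst, 10_000, "linear")
            assert np.min(np.abs(positions - 5000)) > 250

    def test_radius_zero_excludes_only_tss_overlap(self):
        profile = position_profile(2_000)
        tss = [TssRecord("t", 1000, "forward")]
        cfg = DatasetConfig(exclusion_radius=0, seed=1)
        starts = eligible_negative_starts(profile, tss, cfg)
        # brute force: a start s (0-based) is bad iff its window covers 1000
        expected = [
            s for s in range(2000 - 249) if not (s + 1 <= 1000 <= s + 250)
        ]
        assert starts.tolist() == expected

    def test_same_seed_same_windows(self):
        profile = position_profile(10_000)
        tss = [TssRecord("t", 5000, "forward")]
        cfg = DatasetConfig(exclusion_radius=100, seed=77)
        a = sample_negatives(profile, tss, cfg)
        b = sample_negatives(profile, tss, cfg)
        assert [(i.origin, i.strand) for i in a] == [(i.origin, i.strand) for i in b]

    def test_exhausted_pool_raises(self):
        profile = position_profile(1_200)
        tss = [TssRecord("t", 600, "forward")]
        with pytest.raises(SamplingError, match="eligible"):
            sample_negatives(
                profile, tss, DatasetConfig(exclusion_radius=500, seed=0)
            )

    def test_circular_distance_respected(self):
        profile = position_profile(3_000, topology="circular")
        tss = [TssRecord("t", 10, "forward")]  # exclusion zone wraps the origin
        cfg = DatasetConfig(exclusion_radius=250, neg_pos_ratio=3, seed=4)
        for inst in sample_negatives(profile, tss, cfg):
            positions = window_genome_positions(inst, 3000, "circular")
            d = np.abs(positions - 10)
            assert np.min(np.minimum(d, 3000 - d)) > 250


class TestBuildDataset:
    def test_ratio_conservation(self):
        profile = position_profile(20_000)
        tss = [TssRecord(f"t{i}", 1000 + 600 * i, "forward") for i in range(10)]
        dataset = build_dataset(profile, tss, DatasetConfig(seed=3))
        assert dataset.positives == 10
        assert dataset.negatives == 30
        assert len(dataset) == 40

    def test_duplicates_and_out_of_range_dropped(self):
        profile = position_profile(20_000)
        tss = [
            TssRecord("a", 5000, "forward"),
            TssRecord("dup", 5000, "+"),
            TssRecord("edge", 100, "forward"),  # window off the left end
            TssRecord("b", 9000, "reverse"),
        ]
        dataset = build_dataset(profile, tss, DatasetConfig(seed=3))
        assert dataset.positives == 2
        assert dataset.negatives == 6

    def test_empty_positive_class_raises(self):
        profile = position_profile(5_000)
        with pytest.raises(SamplingError):
            build_dataset(profile, [], DatasetConfig(seed=0))


class TestSplitDataset:
    @staticmethod
    def _dummy_dataset(n_pos, n_neg):
        rng = np.random.default_rng(0)
        instances = [
            make_window(rng.normal(size=250), PROMOTER, origin=i + 300)
            for i in range(n_pos)
        ] + [
            make_window(rng.normal(size=250), NON_PROMOTER, origin=i + 300)
            for i in range(n_neg)
        ]
        return LabeledDataset.from_instances(instances, DatasetConfig(seed=8))

    def test_two_thirds_floor_split_of_1648(self):
        dataset = self._dummy_dataset(1648, 4944)
        train, test = split_dataset(dataset)
        assert train.positives == 1098  # floor(2/3 * 1648)
        assert test.positives == 550
        assert train.negatives == 3296  # floor(2/3 * 4944)
        assert test.negatives == 1648

    def test_partition_contract(self):
        dataset = self._dummy_dataset(30, 90)
        train, test = split_dataset(dataset)
        key = lambda inst: (inst.origin, inst.label)
        train_keys = {key(i) for i in train.instances}
        test_keys = {key(i) for i in test.instances}
        assert not train_keys & test_keys
        assert train_keys | test_keys == {key(i) for i in dataset.instances}

    def test_same_seed_same_partition(self):
        dataset = self._dummy_dataset(30, 90)
        a_train, _ = split_dataset(dataset)
        b_train, _ = split_dataset(dataset)
        assert [i.origin for i in a_train.instances] == [
            i.origin for i in b_train.instances
        ]

    def test_tiny_class_raises(self):
        dataset = self._dummy_dataset(1, 10)
        with pytest.raises(SamplingError):
            split_dataset(dataset)


class TestAverageProfile:
    def test_constant_profile_gives_constant_curve(self):
        profile = SiddProfile(np.full(5000, 7.25))
        tss = [TssRecord("t", 2500, "forward"), TssRecord("u", 2000, "reverse")]
        curve = average_profile_around_tss(profile, tss, flank=100)
        assert len(curve) == 200
        assert all(mean == pytest.approx(7.25) for _, mean in curve)

    def test_single_tss_reindexes_the_profile(self):
        profile = position_profile(5000)
        curve = average_profile_around_tss(
            profile, [TssRecord("t", 2500, "forward")], flank=10
        )
        expected = {r: (2500 + r if r < 0 else 2500 + r - 1) for r, _ in curve}
        assert {r: m for r, m in curve} == pytest.approx(expected)

    def test_brute_force_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        values = rng.normal(10, 2, 4000)
        profile = SiddProfile(values)
        tss = [
            TssRecord(f"t{i}", int(p), s)
            for i, (p, s) in enumerate(
                zip(rng.integers(600, 3400, 12), ["forward", "reverse"] * 6)
            )
        ]
        flank = 50
        curve = dict(average_profile_around_tss(profile, tss, flank))
        rels = [r for r in range(-flank, flank + 1) if r != 0]
        for r in rels:
            total = 0.0
            for t in tss:
                if t.strand == "forward":
                    pos = t.position + r if r < 0 else t.position + r - 1
                else:
                    pos = t.position - r if r < 0 else t.position - r + 1
                total += values[pos - 1]
            assert curve[r] == pytest.approx(total / len(tss))

    def test_empty_tss_list_raises(self):
        with pytest.raises(ValueError):
            average_profile_around_tss(position_profile(1000), [], 10)
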