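"""Construction of labeled training/testing sets from a profile and TSS table.

Positive instances are the 250-bp windows −200..+50 around each unique TSS,
read along the direction of transcription.  Negative instances are randomly
selected 250-bp regions kept clear of TSSs: a candidate is rejected if any
of its positions lies within ``exclusion_radius`` bp of any TSS base
(radius 250 for the sumG threshold evaluation, 50 for the neural network,
which benefits from near-promoter negatives).  Negatives outnumber positives
``neg_pos_ratio``:1, and the dataset splits 2/3–1/3 into training and
testing sets, stratified by label.  All randomness is a pure function of the
configured seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import SamplingError, WindowOutOfRangeError
from .sidd_io import (
    CIRCULAR,
    DEFAULT_DOWNSTREAM,
    DEFAULT_UPSTREAM,
    FORWARD,
    NON_PROMOTER,
    PROMOTER,
    REVERSE,
    SiddProfile,
    TssRecord,
    WindowInstance,
    relative_positions,
    window_indices,
)

logger = logging.getLogger(__name__)

# rng stream tags so sampling and splitting draw from distinct seeded streams
_NEGATIVE_STREAM = 1
_SPLIT_STREAM = 2


@dataclass(frozen=True)
class DatasetConfig:
    """Window, ratio, exclusion and split parameters (all lengths in bp)."""

    upstream_extent: int = DEFAULT_UPSTREAM
    downstream_extent: int = DEFAULT_DOWNSTREAM
    neg_pos_ratio: int = 3
    exclusion_radius: int = 250
    train_fraction: float = 2.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.upstream_extent < 0 or self.downstream_extent < 0:
            raise ValueError("window extents must be non-negative")
        if self.window_length < 1:
            raise ValueError("window must span at least one base pair")
        if self.neg_pos_ratio < 1:
            raise ValueError("neg_pos_ratio must be a positive integer")
        if self.exclusion_radius < 0:
            raise ValueError("exclusion_radius must be non-negative")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")

    @property
    def window_length(self) -> int:
        return self.upstream_extent + self.downstream_extent


@dataclass
class LabeledDataset:
    instances: list[WindowInstance]
    config: DatasetConfig
    positives: int
    negatives: int

    @classmethod
    def from_instances(cls, instances, config: DatasetConfig):
        instances = list(instances)
        pos = sum(1 for i in instances if i.label == PROMOTER)
        return cls(instances, config, pos, len(instances) - pos)

    def __len__(self) -> int:
        return len(self.instances)

    def to_arrays(self):
        """(X, y): energy matrix (n, window) and boolean promoter labels."""
        X = np.stack([inst.energies for inst in self.instances])
        y = np.array([inst.label == PROMOTER for inst in self.instances])
        return X, y


def extract_window(
    profile: SiddProfile, tss: TssRecord, config: DatasetConfig | None = None
) -> WindowInstance:
    """Energies at −upstream..−1,+1..+downstream around a TSS.

    Relative +1 is the TSS base itself; reverse-strand windows read along
    decreasing genome coordinates so every window shares the transcription
    orientation.  Circular profiles wrap; on a linear profile a window that
    leaves the sequence raises :class:`WindowOutOfRangeError`.
    """
    config = config or DatasetConfig()
    rel = relative_positions(config.upstream_extent, config.downstream_extent)
    idx = window_indices(
        tss.position, tss.strand, rel, profile.length, profile.topology
    )
    return WindowInstance(
        energies=profile.values[idx],
        label=PROMOTER,
        origin=tss.position,
        strand=tss.strand,
    )


def _excluded_mask(length, topology, tss_positions, radius) -> np.ndarray:
    """Boolean mask (0-based) of positions within ``radius`` of any TSS."""
    mask = np.zeros(length, dtype=bool)
    for pos in tss_positions:
        lo, hi = pos - 1 - radius, pos - 1 + radius
        if topology == CIRCULAR:
            if hi - lo + 1 >= length:
                mask[:] = True
            else:
                mask[np.arange(lo, hi + 1) % length] = True
        else:
            mask[max(lo, 0) : min(hi, length - 1) + 1] = True
    return mask


def eligible_negative_starts(
    profile: SiddProfile, tss_list, config: DatasetConfig
) -> np.ndarray:
    """0-based start positions whose window avoids every TSS exclusion zone."""
    length = profile.length
    window = config.window_length
    if window > length:
        raise SamplingError("window longer than the profile")
    mask = _excluded_mask(
        length,
        profile.topology,
        [t.position for t in tss_list],
        config.exclusion_radius,
    )
    if profile.topology == CIRCULAR:
        # windows may wrap: extend the mask by window-1 positions
        ext = np.concatenate([mask, mask[: window - 1]]).astype(np.int64)
        csum = np.concatenate([[0], np.cumsum(ext)])
        in_window = (csum[window:] - csum[:-window])[:length]
    else:
        counts = np.concatenate([[0], np.cumsum(mask.astype(np.int64))])
        in_window = counts[window:] - counts[:-window]
    return np.flatnonzero(in_window == 0)


def sample_negatives(
    profile: SiddProfile, tss_list, config: DatasetConfig
) -> list[WindowInstance]:
    """Draw ``neg_pos_ratio × |tss_list|`` non-promoter windows.

    Start positions are sampled uniformly without replacement from the
    eligible pool; each window gets a random strand (a background region has
    no transcription direction).  Deterministic given ``config.seed``.
    """
    n_request = config.neg_pos_ratio * len(tss_list)
    eligible = eligible_negative_starts(profile, tss_list, config)
    if eligible.size < n_request:
        raise SamplingError(
            f"only {eligible.size} eligible negative start positions for "
            f"{n_request} requested (exclusion_radius="
            f"{config.exclusion_radius})"
        )
    rng = np.random.default_rng([config.seed, _NEGATIVE_STREAM])
    starts = rng.choice(eligible, size=n_request, replace=False)
    strands = rng.choice(np.array([FORWARD, REVERSE]), size=n_request)
    negatives = []
    for start0, strand in zip(starts, strands):
        first = int(start0) + 1  # 1-based leftmost window position
        if strand == FORWARD:
            origin = first + config.upstream_extent
        else:
            origin = first + config.downstream_extent - 1
        if profile.topology == CIRCULAR:
            origin = (origin - 1) % profile.length + 1
        pseudo = TssRecord(f"neg_{first}", origin, strand)
        inst = extract_window(profile, pseudo, config)
        inst.label = NON_PROMOTER
        negatives.append(inst)
    return negatives


def build_dataset(
    profile: SiddProfile, tss_list, config: DatasetConfig | None = None
) -> LabeledDataset:
    """One promoter window per unique TSS plus ratio-matched negatives.

    Duplicate (position, strand) TSSs collapse to the earliest record.  On a
    linear profile, TSSs whose window would run off an end are dropped with
    a warning rather than padded (padding would invent energies).
    """
    config = config or DatasetConfig()
    seen: set[tuple[int, str]] = set()
    kept: list[TssRecord] = []
    dropped = 0
    for tss in tss_list:
        key = (tss.position, tss.strand)
        if key in seen:
            continue
        seen.add(key)
        if not 1 <= tss.position <= profile.length:
            raise WindowOutOfRangeError(
                f"TSS {tss.id!r} position {tss.position} outside profile"
            )
        try:
            # probe window fit now so counts are known before sampling
            extract_window(profile, tss, config)
        except WindowOutOfRangeError:
            dropped += 1
            logger.warning(
                "stage=build_dataset dropped_tss=%s position=%d strand=%s "
                "reason=window_out_of_range",
                tss.id,
                tss.position,
                tss.strand,
            )
            continue
        kept.append(tss)
    if not kept:
        raise SamplingError("no usable TSS records (empty positive class)")
    positives = [extract_window(profile, tss, config) for tss in kept]
    negatives = sample_negatives(profile, kept, config)
    logger.info(
        "stage=build_dataset tss_read=%d tss_dropped=%d positives=%d negatives=%d",
        len(seen),
        dropped,
        len(positives),
        len(negatives),
    )
    return LabeledDataset.from_instances(positives + negatives, config)


def split_dataset(dataset: LabeledDataset, config: DatasetConfig | None = None):
    """Seeded stratified split into (training, testing).

    Each class is split as close to ``train_fraction`` as rounding allows,
    flooring on the training side; the partitions are disjoint and their
    union is the input.
    """
    config = config or dataset.config
    rng = np.random.default_rng([config.seed, _SPLIT_STREAM])
    train_instances: list = []
    test_instances: list = []
    for label in (PROMOTER, NON_PROMOTER):
        members = [i for i in dataset.instances if i.label == label]
        if len(members) < 2:
            raise SamplingError(
                f"class {label!r} has {len(members)} instance(s); "
                "cannot split into two non-empty partitions"
            )
        order = rng.permutation(len(members))
        n_train = math.floor(config.train_fraction * len(members))
        n_train = min(max(n_train, 1), len(members) - 1)
        idx_train = set(order[:n_train].tolist())
        train_instances.extend(m for k, m in enumerate(members) if k in idx_train)
        test_instances.extend(m for k, m in enumerate(members) if k not in idx_train)
    return (
        LabeledDataset.from_instances(train_instances, config),
        LabeledDataset.from_instances(test_instances, config),
    )


def average_profile_around_tss(
    profile: SiddProfile, tss_list, flank: int
) -> list[tuple[int, float]]:
    """Mean G at each relative position −flank..+flank (no 0) over TSSs.

    Orientation-corrected per strand.  On a linear profile, TSSs whose
    ±flank neighbourhood does not fit are skipped; on a circular profile all
    TSSs contribute with wrapping.  This reproduces the classic averaged
    SIDD energy diagnostic: a well centred near the TSS, rising with
    distance, more steeply downstream.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    tss_list = list(tss_list)
    if not tss_list:
        raise ValueError("empty TSS list")
    rel = relative_positions(flank, flank)
    total = np.zeros(rel.size)
    used = 0
    for tss in tss_list:
        try:
            idx = window_indices(
                tss.position, tss.strand, rel, profile.length, profile.topology
            )
        except WindowOutOfRangeError:
            continue
        total += profile.values[idx]
        used += 1
    if used == 0:
        raise SamplingError("no TSS neighbourhood fits inside the profile")
    means = total / used
    return [(int(r), float(m)) for r, m in zip(rel, means)]
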