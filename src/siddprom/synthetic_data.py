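"""Synthetic SIDD profiles and TSS tables with promoter-like energy wells.

Real SIDD tracks show a characteristic averaged shape around transcription
start sites: the lowest destabilization energies sit near the TSS and rise
with distance, more steeply downstream than upstream.  The generator
emulates exactly that statistical structure over a smoothed Gaussian
background:

* background — white noise smoothed by a moving average (``smoothing_bp``
  correlation length), rescaled to ``background_mean``/``background_sd``
  kcal/mol;
* promoters — at each planted TSS an energy *well* is subtracted:
  ``well_depth · exp(−d / decay)`` with separate upstream and downstream
  decay scales (downstream shorter, reproducing the asymmetry);
* ``pattern_only`` mode — the well is re-centred to sum to zero across the
  −200..+50 window, so promoter and background windows have *equal expected
  sumG* while keeping distinct positional shape.  This isolates the claim
  that a network can exploit positional patterns a summed-energy threshold
  cannot see.

Everything is a pure function of the config (including its seed).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .errors import SamplingError
from .sidd_io import (
    CIRCULAR,
    DEFAULT_DOWNSTREAM,
    DEFAULT_UPSTREAM,
    FORWARD,
    LINEAR,
    REVERSE,
    SiddProfile,
    TssRecord,
    relative_positions,
    window_indices,
)

#: Half-width of the averaged-profile diagnostic and of the planted well in
#: normal mode; linear genomes keep this margin free of TSSs so every
#: neighbourhood fits.
WELL_FLANK = 500
_LINEAR_MARGIN = WELL_FLANK + 1


@dataclass(frozen=True)
class SynthConfig:
    genome_length: int = 100_000
    n_promoters: int = 100
    background_mean: float = 10.0
    background_sd: float = 1.5
    well_depth: float = 6.0
    upstream_decay: float = 180.0
    downstream_decay: float = 90.0
    pattern_only: bool = False
    smoothing_bp: int = 25
    min_tss_spacing: int = 0
    seed: int = 0
    topology: str = LINEAR
    upstream_extent: int = DEFAULT_UPSTREAM
    downstream_extent: int = DEFAULT_DOWNSTREAM

    def __post_init__(self) -> None:
        if self.genome_length < 1 or self.n_promoters < 1:
            raise ValueError("genome_length and n_promoters must be positive")
        if self.background_sd <= 0:
            raise ValueError("background_sd must be positive")
        if self.well_depth < 0:
            raise ValueError("well_depth must be non-negative")
        if self.upstream_decay <= 0 or self.downstream_decay <= 0:
            raise ValueError("decay scales must be positive")
        if self.smoothing_bp < 1:
            raise ValueError("smoothing_bp must be a positive integer")
        if self.min_tss_spacing < 0:
            raise ValueError("min_tss_spacing must be non-negative")
        if self.topology not in (LINEAR, CIRCULAR):
            raise ValueError(f"unknown topology: {self.topology!r}")
        window = self.upstream_extent + self.downstream_extent
        if self.n_promoters * (window + self.min_tss_spacing) > self.genome_length:
            raise ValueError(
                "n_promoters x (window + min_tss_spacing) exceeds the genome"
            )
        if self.topology == LINEAR and self.genome_length < 2 * _LINEAR_MARGIN + 1:
            raise ValueError(
                f"linear genomes must be at least {2 * _LINEAR_MARGIN + 1} bp "
                "so promoter neighbourhoods fit"
            )


@dataclass
class GroundTruth:
    """Machine-readable record of what was planted: config echo + TSS list."""

    config: SynthConfig
    tss: list[TssRecord]

    def to_text(self) -> str:
        payload = {
            "config": asdict(self.config),
            "n_tss": len(self.tss),
            "tss": [
                {"id": t.id, "position": t.position, "strand": t.strand}
                for t in self.tss
            ],
        }
        return yaml.safe_dump(payload, sort_keys=True)

    @classmethod
    def from_text(cls, text: str) -> "GroundTruth":
        payload = yaml.safe_load(text)
        config = SynthConfig(**payload["config"])
        tss = [
            TssRecord(t["id"], t["position"], t["strand"])
            for t in payload["tss"]
        ]
        return cls(config=config, tss=tss)


def describe_truth(truth: GroundTruth) -> str:
    return truth.to_text()


def _smoothed_background(rng, config: SynthConfig) -> np.ndarray:
    raw = rng.normal(size=config.genome_length)
    k = config.smoothing_bp
    if k > 1:
        kernel = np.ones(k) / k
        if config.topology == CIRCULAR:
            pad_left = raw[-(k // 2) :] if k // 2 else raw[:0]
            pad_right = raw[: k - 1 - k // 2]
            raw = np.convolve(
                np.concatenate([pad_left, raw, pad_right]), kernel, "valid"
            )
        else:
            raw = np.convolve(raw, kernel, "same")
    raw = (raw - raw.mean()) / raw.std()
    return config.background_mean + config.background_sd * raw


def _genome_distance(a: int, b: int, length: int, topology: str) -> int:
    d = abs(a - b)
    return min(d, length - d) if topology == CIRCULAR else d


def _place_tss(rng, config: SynthConfig) -> list[int]:
    if config.topology == LINEAR:
        low, high = _LINEAR_MARGIN + 1, config.genome_length - _LINEAR_MARGIN
    else:
        low, high = 1, config.genome_length
    if high < low:
        raise SamplingError("genome too short to place any TSS")
    spacing = max(config.min_tss_spacing, 1)
    positions: list[int] = []
    attempts = 0
    limit = 200 * config.n_promoters
    while len(positions) < config.n_promoters:
        attempts += 1
        if attempts > limit:
            raise SamplingError(
                f"could not place {config.n_promoters} TSSs with spacing "
                f">= {config.min_tss_spacing} in {attempts} attempts"
            )
        cand = int(rng.integers(low, high + 1))
        if all(
            _genome_distance(cand, p, config.genome_length, config.topology)
            >= spacing
            for p in positions
        ):
            positions.append(cand)
    return sorted(positions)


def _well_shape(rel: np.ndarray, config: SynthConfig) -> np.ndarray:
    """well_depth · exp(−d/decay) at each relative position (d = 0 at +1)."""
    dist = np.where(rel < 0, -rel, rel - 1).astype(np.float64)
    decay = np.where(rel < 0, config.upstream_decay, config.downstream_decay)
    return config.well_depth * np.exp(-dist / decay)


def generate(config: SynthConfig):
    """Build (profile, TSS records, ground truth) from a config."""
    rng = np.random.default_rng(config.seed)
    values = _smoothed_background(rng, config)
    positions = _place_tss(rng, config)
    strands = rng.choice(np.array([FORWARD, REVERSE]), size=len(positions))
    tss = [
        TssRecord(f"tss_{i + 1:04d}", pos, strand)
        for i, (pos, strand) in enumerate(zip(positions, strands))
    ]
    if config.well_depth > 0:
        if config.pattern_only:
            rel = relative_positions(
                config.upstream_extent, config.downstream_extent
            )
            shape = _well_shape(rel, config)
            shape = shape - shape.mean()  # zero-sum across the window
        else:
            rel = relative_positions(WELL_FLANK, WELL_FLANK)
            shape = _well_shape(rel, config)
        for record in tss:
            idx = window_indices(
                record.position,
                record.strand,
                rel,
                config.genome_length,
                config.topology,
            )
            values[idx] -= shape
    profile = SiddProfile(values, topology=config.topology, name="synthetic")
    return profile, tss, GroundTruth(config=config, tss=tss)
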