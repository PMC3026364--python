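"""Reading and writing SIDD energy tracks, TSS tables and window datasets.

This module owns every coordinate convention in the package:

* Genome coordinates are 1-based inclusive at all external interfaces
  (GenBank / RegulonDB style); internal array storage is 0-based.  The
  conversion happens here and nowhere else.
* Windows around a transcription start site (TSS) are indexed by relative
  position -upstream..-1, +1..+downstream with **no position 0**; relative
  +1 is the TSS base itself.  With the default extents (200 upstream, 50
  downstream) a window holds exactly 250 energies.
* A profile describes a single replicon, either ``linear`` or ``circular``.
  On a circular profile window indices wrap modulo the genome length.

Supported file formats: bedGraph (0-based half-open) and fixed-step wiggle
(step 1) for energy tracks, and plain tab-separated tables for TSSs and
labeled window datasets.  Tracks must be dense: every base pair from 1 to
the genome length carries exactly one value.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DatasetFormatError,
    ProfileFormatError,
    TssTableError,
    WindowOutOfRangeError,
)

FORWARD = "forward"
REVERSE = "reverse"
PROMOTER = "promoter"
NON_PROMOTER = "non-promoter"

LINEAR = "linear"
CIRCULAR = "circular"

#: Window extents used throughout the package (bp upstream / downstream of
#: the TSS along the direction of transcription).
DEFAULT_UPSTREAM = 200
DEFAULT_DOWNSTREAM = 50
WINDOW_LENGTH = DEFAULT_UPSTREAM + DEFAULT_DOWNSTREAM

_STRAND_ALIASES = {
    "+": FORWARD,
    "forward": FORWARD,
    "-": REVERSE,
    "reverse": REVERSE,
}


def normalize_strand(strand: str) -> str:
    """Map ``+``/``-``/``forward``/``reverse`` onto the canonical names."""
    try:
        return _STRAND_ALIASES[str(strand).strip()]
    except KeyError:
        raise TssTableError(f"unknown strand value: {strand!r}") from None


@dataclass
class SiddProfile:
    """A dense per-base-pair destabilization free-energy track G(x).

    ``values[i]`` is the free energy (kcal/mol) of the base pair at 1-based
    genome position ``i + 1``.
    """

    values: np.ndarray
    topology: str = LINEAR
    name: str = "profile"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ProfileFormatError("profile must hold at least one value")
        if not np.all(np.isfinite(self.values)):
            raise ProfileFormatError("profile contains non-finite values")
        if self.topology not in (LINEAR, CIRCULAR):
            raise ValueError(f"unknown topology: {self.topology!r}")

    @property
    def length(self) -> int:
        return int(self.values.size)

    def energy_at(self, position: int) -> float:
        """Energy at a 1-based genome position."""
        if not 1 <= position <= self.length:
            raise WindowOutOfRangeError(
                f"position {position} outside 1..{self.length}"
            )
        return float(self.values[position - 1])


@dataclass(frozen=True)
class TssRecord:
    """A transcription start site: identifier, 1-based position, strand."""

    id: str
    position: int
    strand: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise TssTableError(
                f"TSS {self.id!r}: position {self.position} is not 1-based"
            )
        object.__setattr__(self, "strand", normalize_strand(self.strand))


@dataclass
class WindowInstance:
    """A labeled window of energies ordered by relative position.

    ``energies[k]`` corresponds to the k-th relative position of
    ``relative_positions(...)``; ``origin`` is the genome coordinate of
    relative position +1 (the TSS base for promoter windows).
    """

    energies: np.ndarray
    label: str
    origin: int
    strand: str

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=np.float64)
        if self.energies.ndim != 1:
            raise ValueError("window energies must be one-dimensional")
        if self.label not in (PROMOTER, NON_PROMOTER):
            raise ValueError(f"unknown label: {self.label!r}")
        self.strand = normalize_strand(self.strand)


def relative_positions(
    upstream: int = DEFAULT_UPSTREAM, downstream: int = DEFAULT_DOWNSTREAM
) -> np.ndarray:
    """Relative window positions -upstream..-1, +1..+downstream (no 0)."""
    if upstream < 0 or downstream < 0 or upstream + downstream < 1:
        raise ValueError("window extents must be non-negative and non-empty")
    return np.concatenate(
        [np.arange(-upstream, 0), np.arange(1, downstream + 1)]
    )


def window_indices(
    origin: int,
    strand: str,
    rel: np.ndarray,
    length: int,
    topology: str,
) -> np.ndarray:
    """Map relative window positions to 0-based profile indices.

    Windows are read along the direction of transcription: on the forward
    strand relative position r maps to genome position ``origin + r`` for
    r < 0 and ``origin + r - 1`` for r >= 1; on the reverse strand upstream
    means higher genome coordinates and the mapping mirrors.  On a circular
    profile indices wrap modulo ``length``.
    """
    strand = normalize_strand(strand)
    if not 1 <= origin <= length:
        raise WindowOutOfRangeError(f"origin {origin} outside 1..{length}")
    rel = np.asarray(rel, dtype=np.int64)
    step = (rel > 0).astype(np.int64)  # skip the non-existent position 0
    if strand == FORWARD:
        pos = origin + rel - step
    else:
        pos = origin - rel + step
    idx = pos - 1
    if topology == CIRCULAR:
        return np.mod(idx, length)
    if idx.min() < 0 or idx.max() >= length:
        raise WindowOutOfRangeError(
            f"window around origin {origin} ({strand}) leaves the linear "
            f"profile of length {length}"
        )
    return idx


# ---------------------------------------------------------------------------
# SIDD energy tracks (bedGraph / fixed-step wiggle)
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("track", "browser", "#")


def _data_lines(path):
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line


def read_profile(path, topology: str = LINEAR, name: str | None = None) -> SiddProfile:
    """Read a dense per-bp energy track from bedGraph or fixed-step wiggle.

    The file must cover every base pair from position 1 to the end of the
    replicon exactly once; gaps, overlaps and multiple chromosomes are
    rejected (single-replicon scope).
    """
    lines = list(_data_lines(path))
    if not lines:
        raise ProfileFormatError(f"{path}: no data lines")
    first = lines[0][1]
    if first.startswith("variableStep"):
        raise ProfileFormatError(f"{path}: variableStep wiggle is not supported")
    if first.startswith("fixedStep"):
        chrom, values = _parse_wiggle(path, lines)
    else:
        chrom, values = _parse_bedgraph(path, lines)
    return SiddProfile(values, topology=topology, name=name or chrom)


def _parse_wiggle(path, lines):
    chrom = None
    next_pos = 1  # 1-based position the next value must describe
    values: list[float] = []
    in_block = False
    for lineno, line in lines:
        if line.startswith("fixedStep"):
            fields = dict(
                item.split("=", 1) for item in line.split()[1:] if "=" in item
            )
            block_chrom = fields.get("chrom")
            if chrom is None:
                chrom = block_chrom
            elif block_chrom != chrom:
                raise ProfileFormatError(
                    f"{path}:{lineno}: multiple chromosomes "
                    f"({chrom!r} and {block_chrom!r}); single-replicon scope"
                )
            if fields.get("step", "1") != "1" or fields.get("span", "1") != "1":
                raise ProfileFormatError(
                    f"{path}:{lineno}: only step=1 span=1 wiggle is supported"
                )
            start = int(fields.get("start", "1"))
            if start != next_pos:
                kind = "gap" if start > next_pos else "overlap"
                raise ProfileFormatError(
                    f"{path}:{lineno}: {kind} — block starts at {start}, "
                    f"expected {next_pos} (track must be dense)"
                )
            in_block = True
            continue
        if not in_block:
            raise ProfileFormatError(
                f"{path}:{lineno}: value before any fixedStep header"
            )
        try:
            values.append(float(line))
        except ValueError:
            raise ProfileFormatError(
                f"{path}:{lineno}: non-numeric value {line!r}"
            ) from None
        next_pos += 1
    return chrom or "profile", np.asarray(values, dtype=np.float64)


def _parse_bedgraph(path, lines):
    chrom = None
    intervals = []  # (start0, end0, value)
    for lineno, line in lines:
        fields = line.split()
        if len(fields) != 4:
            raise ProfileFormatError(
                f"{path}:{lineno}: expected 4 bedGraph columns, got {len(fields)}"
            )
        if chrom is None:
            chrom = fields[0]
        elif fields[0] != chrom:
            raise ProfileFormatError(
                f"{path}:{lineno}: multiple chromosomes "
                f"({chrom!r} and {fields[0]!r}); single-replicon scope"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
            value = float(fields[3])
        except ValueError:
            raise ProfileFormatError(
                f"{path}:{lineno}: non-numeric bedGraph fields"
            ) from None
        if not np.isfinite(value):
            raise ProfileFormatError(f"{path}:{lineno}: non-finite value")
        if end <= start or start < 0:
            raise ProfileFormatError(
                f"{path}:{lineno}: bad interval [{start}, {end})"
            )
        intervals.append((start, end, value))
    intervals.sort(key=lambda iv: iv[0])
    cursor = 0
    for start, end, _ in intervals:
        if start < cursor:
            raise ProfileFormatError(
                f"{path}: overlapping intervals at 0-based position {start}"
            )
        if start > cursor:
            raise ProfileFormatError(
                f"{path}: gap — positions {cursor}..{start - 1} (0-based) "
                "have no value (track must be dense)"
            )
        cursor = end
    lengths = np.array([end - start for start, end, _ in intervals])
    vals = np.array([value for _, _, value in intervals])
    return chrom, np.repeat(vals, lengths)


def write_profile(profile: SiddProfile, path, fmt: str | None = None) -> None:
    """Write a profile as bedGraph or wiggle (chosen by ``fmt`` or extension)."""
    if fmt is None:
        s = str(path).lower()
        fmt = "wiggle" if s.endswith((".wig", ".wiggle")) else "bedgraph"
    if fmt not in ("bedgraph", "wiggle"):
        raise ValueError(f"unknown profile format: {fmt!r}")
    buf = io.StringIO()
    if fmt == "wiggle":
        buf.write(f"fixedStep chrom={profile.name} start=1 step=1\n")
        for v in profile.values:
            buf.write(f"{v:.12g}\n")
    else:
        values = profile.values
        # run-length encode stretches of identical values
        boundaries = np.flatnonzero(np.diff(values)) + 1
        starts = np.concatenate([[0], boundaries])
        ends = np.concatenate([boundaries, [values.size]])
        for s, e in zip(starts, ends):
            buf.write(f"{profile.name}\t{s}\t{e}\t{values[s]:.12g}\n")
    with open(path, "w") as handle:
        handle.write(buf.getvalue())


# ---------------------------------------------------------------------------
# TSS tables
# ---------------------------------------------------------------------------


def read_tss_table(path) -> list[TssRecord]:
    """Read a tab-separated TSS table (id, 1-based position, strand).

    A header row is detected by a non-integer position field.  Duplicate
    (position, strand) pairs collapse to a single record, keeping the
    earliest identifier — mirroring a table filtered for unique promoters.
    """
    records: list[TssRecord] = []
    seen: set[tuple[int, str]] = set()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise TssTableError(
                    f"{path}:{lineno}: expected 3 tab-separated columns"
                )
            ident, pos_text, strand = fields[0], fields[1], fields[2]
            try:
                position = int(pos_text)
            except ValueError:
                # a header row has a non-numeric position AND no real strand
                if lineno == 1 and strand.strip() not in _STRAND_ALIASES:
                    continue
                raise TssTableError(
                    f"{path}:{lineno}: non-integer position {pos_text!r}"
                ) from None
            record = TssRecord(ident, position, strand)
            key = (record.position, record.strand)
            if key in seen:
                continue
            seen.add(key)
            records.append(record)
    return records


def write_tss_table(records, path) -> None:
    with open(path, "w") as handle:
        handle.write("id\tposition\tstrand\n")
        for rec in records:
            handle.write(f"{rec.id}\t{rec.position}\t{rec.strand}\n")


# ---------------------------------------------------------------------------
# Window datasets
# ---------------------------------------------------------------------------


def _energy_columns(n: int) -> list[str]:
    if n == WINDOW_LENGTH:
        rel = relative_positions()
    else:
        rel = np.arange(1, n + 1)
    return [f"G{r:+d}" for r in rel]


def write_dataset(instances, path) -> None:
    """Write windows as TSV: origin, strand, label, then the energy columns."""
    instances = list(instances)
    n_energy = instances[0].energies.size if instances else WINDOW_LENGTH
    header = ["origin", "strand", "label"] + _energy_columns(n_energy)
    with open(path, "w") as handle:
        handle.write("\t".join(header) + "\n")
        for inst in instances:
            if inst.energies.size != n_energy:
                raise DatasetFormatError("mixed window lengths in one dataset")
            energy_text = "\t".join(f"{v:.12g}" for v in inst.energies)
            handle.write(
                f"{inst.origin}\t{inst.strand}\t{inst.label}\t{energy_text}\n"
            )


def read_dataset(path) -> list[WindowInstance]:
    """Read a window dataset written by :func:`write_dataset`."""
    instances: list[WindowInstance] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:3] != ["origin", "strand", "label"]:
            raise DatasetFormatError(f"{path}: unrecognized dataset header")
        n_energy = len(header) - 3
        for lineno, raw in enumerate(handle, start=2):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != n_energy + 3:
                raise DatasetFormatError(
                    f"{path}:{lineno}: expected {n_energy + 3} columns, "
                    f"got {len(fields)}"
                )
            try:
                origin = int(fields[0])
                energies = np.asarray(fields[3:], dtype=np.float64)
            except ValueError:
                raise DatasetFormatError(
                    f"{path}:{lineno}: malformed numeric field"
                ) from None
            instances.append(
                WindowInstance(energies, fields[2], origin, fields[1])
            )
    return instances
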