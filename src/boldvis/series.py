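"""Core time-series containers and condition-based segmentation.

A :class:`TimeSeries` holds uniformly sampled BOLD-like values ``y_i`` at
strictly increasing times ``t_i``; a :class:`BlockDesign` holds the task
condition label of every sample (``word`` / ``nonword`` / ``rest``) in a
block paradigm.  :func:`extract_condition` slices a series into the samples
carrying one label, either as one concatenated series or as one series per
contiguous block, so that condition-specific visibility networks can be
built downstream.

All node labels and sample indices are 0-based.  For graph construction the
times are taken as integer sample indices: the visibility criterion is
invariant under uniform rescaling of the time axis, so nothing is lost for
uniformly sampled data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "CONDITIONS",
    "TimeSeries",
    "BlockDesign",
    "ConditionSeries",
    "SeriesFormatError",
    "extract_condition",
    "read_series",
    "write_series",
    "read_design",
    "write_design",
]

#: Recognised task condition labels.
CONDITIONS = ("word", "nonword", "rest")

SegmentationMode = Literal["concatenated", "per_block"]


class SeriesFormatError(ValueError):
    """Raised when a series/design file cannot be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class TimeSeries:
    """Ordered real-valued samples with a uniform sampling interval.

    Parameters
    ----------
    values
        Sample values ``y_i`` in arbitrary BOLD units.
    times
        Sample times ``t_i``, strictly increasing.  Defaults to the integer
        sample indices ``0..n-1``.
    sampling_interval
        Seconds per sample (metadata; 3 s in the block design emulated here).
    """

    values: np.ndarray
    times: np.ndarray = None  # type: ignore[assignment]
    sampling_interval: float = 1.0

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        times = self.times
        if times is None:
            times = np.arange(len(values), dtype=float)
        times = np.asarray(times, dtype=float)
        if len(times) != len(values):
            raise ValueError(
                f"times length {len(times)} != values length {len(values)}"
            )
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TimeSeries):
            return NotImplemented
        return (
            len(self) == len(other)
            and np.array_equal(self.values, other.values)
            and np.array_equal(self.times, other.times)
            and self.sampling_interval == other.sampling_interval
        )


@dataclass(frozen=True)
class BlockDesign:
    """Condition label per sample of a block-design acquisition."""

    labels: tuple[str, ...]

    def __post_init__(self):
        labels = tuple(self.labels)
        bad = sorted(set(labels) - set(CONDITIONS))
        if bad:
            raise ValueError(f"unknown condition labels {bad}; allowed: {CONDITIONS}")
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.labels)

    def runs(self, condition: str) -> list[tuple[int, int]]:
        """Maximal runs of ``condition`` as half-open ``(start, stop)`` index ranges."""
        out: list[tuple[int, int]] = []
        start = None
        for i, lab in enumerate(self.labels):
            if lab == condition and start is None:
                start = i
            elif lab != condition and start is not None:
                out.append((start, i))
                start = None
        if start is not None:
            out.append((start, len(self.labels)))
        return out


@dataclass(frozen=True)
class ConditionSeries:
    """Samples of one condition, either concatenated or split per block.

    ``source_ranges`` records the half-open index ranges in the parent series
    that each segment was taken from, in temporal order; for the concatenated
    mode there is a single segment assembled from all ranges.
    """

    condition: str
    mode: SegmentationMode
    segments: tuple[TimeSeries, ...]
    source_ranges: tuple[tuple[int, int], ...]

    @property
    def n_samples(self) -> int:
        return sum(len(s) for s in self.segments)


def extract_condition(
    ts: TimeSeries,
    design: BlockDesign,
    condition: str,
    mode: SegmentationMode = "concatenated",
) -> ConditionSeries:
    """Slice ``ts`` down to the samples labelled ``condition``.

    ``per_block`` yields one segment per maximal run of the label, each
    keeping its source times; ``concatenated`` joins the runs end-to-end
    into one series re-indexed ``0..m-1``.  Sample order is preserved and no
    sample is duplicated or dropped.
    """
    if len(design) != len(ts):
        raise ValueError(f"design length {len(design)} != series length {len(ts)}")
    if mode not in ("concatenated", "per_block"):
        raise ValueError(f"unknown segmentation mode {mode!r}")
    ranges = design.runs(condition)
    if not ranges:
        raise ValueError(f"condition {condition!r} does not occur in the design")
    if mode == "per_block":
        segments = tuple(
            TimeSeries(
                ts.values[a:b], ts.times[a:b], sampling_interval=ts.sampling_interval
            )
            for a, b in ranges
        )
    else:
        values = np.concatenate([ts.values[a:b] for a, b in ranges])
        segments = (
            TimeSeries(values, sampling_interval=ts.sampling_interval),
        )
    return ConditionSeries(
        condition=condition,
        mode=mode,
        segments=segments,
        source_ranges=tuple(ranges),
    )


# ---------------------------------------------------------------------------
# Plain-text I/O: two columns (sample_index, value), comma or tab separated,
# optional single header line.  Round-trips exactly at %.17g precision.
# ---------------------------------------------------------------------------


def _split_row(line: str) -> list[str]:
    sep = "," if "," in line else "\t"
    return [tok.strip() for tok in line.split(sep)]


def write_series(ts: TimeSeries, path: str | Path) -> None:
    """Write a series as ``sample_index,value`` CSV with a header line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_index,value\n")
        for t, y in zip(ts.times, ts.values):
            fh.write(f"{t:.17g},{y:.17g}\n")


def read_series(path: str | Path, sampling_interval: float = 1.0) -> TimeSeries:
    """Read a two-column (time, value) text file.

    Tolerates one header line and both comma and tab delimiters.  Raises
    :class:`SeriesFormatError` with the offending line number for non-numeric
    rows or non-increasing times, and for series shorter than 2 samples
    (too short for any graph construction).
    """
    path = Path(path)
    times: list[float] = []
    values: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = _split_row(line)
            if len(toks) < 2:
                raise SeriesFormatError(f"expected 2 columns, got {len(toks)}", lineno)
            try:
                t, y = float(toks[0]), float(toks[1])
            except ValueError:
                if lineno == 1:
                    continue  # header line
                raise SeriesFormatError(f"non-numeric row {toks!r}", lineno) from None
            if times and t <= times[-1]:
                raise SeriesFormatError(
                    f"times not strictly increasing ({t} after {times[-1]})", lineno
                )
            times.append(t)
            values.append(y)
    if len(values) < 2:
        raise SeriesFormatError(
            f"series has {len(values)} samples; at least 2 are required"
        )
    return TimeSeries(
        np.array(values), np.array(times), sampling_interval=sampling_interval
    )


def write_design(design: BlockDesign, path: str | Path) -> None:
    """Write the condition label sidecar as ``sample_index,condition`` CSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_index,condition\n")
        for i, lab in enumerate(design.labels):
            fh.write(f"{i},{lab}\n")


def read_design(path: str | Path) -> BlockDesign:
    """Read a ``sample_index,condition`` sidecar file."""
    path = Path(path)
    labels: list[str] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            toks = _split_row(line)
            if len(toks) < 2:
                raise SeriesFormatError(f"expected 2 columns, got {len(toks)}", lineno)
            if toks[1] not in CONDITIONS:
                if lineno == 1:
                    continue
                raise SeriesFormatError(f"unknown condition {toks[1]!r}", lineno)
            labels.append(toks[1])
    if not labels:
        raise SeriesFormatError("design file contains no labelled samples")
    return BlockDesign(tuple(labels))
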