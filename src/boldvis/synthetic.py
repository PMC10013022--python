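"""Synthetic block-design BOLD time-series generator.

Emulates the acquisition structure of a reading-task fMRI study: 240 samples
at a 3 s repetition time, three cycles of 80 samples each following the
section order words -> rest -> nonwords -> rest with 20 samples per section.
Each synthetic subject is

    y(t) = baseline + (boxcar of per-condition amplitudes * canonical HRF)(t)
           + AR(1) Gaussian noise,

where the hemodynamic response function (HRF) is the standard double-gamma
shape (peak at ~6 s, undershoot at ~16 s, undershoot ratio 1/6) normalised
to unit peak so that the amplitudes are peak responses in BOLD units, and
the lag-1 autoregressive noise controls the roughness of the series — the
property that drives visibility-graph clique structure.  Cohorts of subjects
are simulated independently and averaged pointwise, mirroring an analysis
that averages the regional series over the members of each group before
network construction.

The generator is a stand-in for real regional BOLD averages: it reproduces
their timing structure, task-locked response and smoothness, not any spatial
or neurovascular detail.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import gamma as _gamma

from .series import CONDITIONS, BlockDesign, TimeSeries

__all__ = [
    "BlockDesignSpec",
    "BoldParams",
    "CohortSpec",
    "POPULATION_PRESETS",
    "REGION_PRESETS",
    "make_design",
    "double_gamma_hrf",
    "simulate_subject",
    "simulate_cohort",
    "average_cohort",
]


@dataclass(frozen=True)
class BlockDesignSpec:
    """Block paradigm layout: cycles of fixed-length condition sections.

    The defaults reproduce the emulated study design: 3 cycles x 4 sections
    (word, rest, nonword, rest) x 20 samples at 3 s = 240 samples, 12 min.
    """

    n_cycles: int = 3
    points_per_section: int = 20
    section_order: tuple[str, ...] = ("word", "rest", "nonword", "rest")
    sampling_interval: float = 3.0

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be a positive integer")
        if self.points_per_section < 1:
            raise ValueError("points_per_section must be a positive integer")
        order = tuple(self.section_order)
        if not order:
            raise ValueError("section_order must be nonempty")
        bad = sorted(set(order) - set(CONDITIONS))
        if bad:
            raise ValueError(f"unknown section labels {bad}; allowed: {CONDITIONS}")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        object.__setattr__(self, "section_order", order)

    @property
    def total_length(self) -> int:
        return self.n_cycles * self.points_per_section * len(self.section_order)


@dataclass(frozen=True)
class BoldParams:
    """Parameters of the per-subject generative model.

    ``baseline`` and the amplitudes are in arbitrary BOLD units; the
    amplitudes are the peak evoked response added during the respective task
    sections (2 on a baseline of 100 is a typical ~2% block-design signal
    change).  The three ``hrf_*`` fields shape the double-gamma response (in
    seconds, converted by the sampling interval).  ``ar_coefficient`` is the
    lag-1 autoregressive coefficient of the noise, in (-1, 1);
    ``noise_sd`` is the innovation standard deviation.
    """

    baseline: float = 100.0
    amplitude_word: float = 2.0
    amplitude_nonword: float = 2.0
    hrf_peak_delay: float = 6.0
    hrf_undershoot_delay: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    ar_coefficient: float = 0.4
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not -1.0 < self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie strictly in (-1, 1)")
        if self.hrf_peak_delay <= 0 or self.hrf_undershoot_delay <= 0:
            raise ValueError("HRF delays must be positive")
        if self.hrf_undershoot_ratio < 0:
            raise ValueError("hrf_undershoot_ratio must be >= 0")


#: Population presets: the adult/child contrast is modelled purely as a
#: smoothness/noise parameter pair (smoother, less noisy series produce
#: higher-dimensional cliques in the visibility graph), not as a biological
#: claim.
POPULATION_PRESETS: dict[str, dict[str, float]] = {
    "adults": {"ar_coefficient": 0.4, "noise_sd": 1.0},
    "children": {"ar_coefficient": 0.8, "noise_sd": 0.6},
}

#: Region presets: high task activity (e.g. left putamen) vs low activity
#: (e.g. lingual gyrus), expressed as evoked-response amplitude.
REGION_PRESETS: dict[str, dict[str, float]] = {
    "high_activity": {"amplitude_word": 2.0, "amplitude_nonword": 2.0},
    "low_activity": {"amplitude_word": 0.4, "amplitude_nonword": 0.4},
}


@dataclass(frozen=True)
class CohortSpec:
    """A group of subjects sharing one design and one parameter set."""

    n_subjects: int = 5
    bold_params: BoldParams = field(default_factory=BoldParams)
    design: BlockDesignSpec = field(default_factory=BlockDesignSpec)
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")


def make_design(spec: BlockDesignSpec) -> BlockDesign:
    """Expand a design spec into the per-sample label sequence."""
    cycle = tuple(
        lab for lab in spec.section_order for _ in range(spec.points_per_section)
    )
    return BlockDesign(cycle * spec.n_cycles)


def double_gamma_hrf(
    sampling_interval: float,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    duration: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``sampling_interval``.

    Both gamma densities use unit dispersion (shape = delay in seconds,
    scale = 1 s), the field-standard canonical shape.  The kernel is
    normalised to unit peak so that convolving a unit boxcar yields a
    response whose plateau is the boxcar amplitude.
    """
    t = np.arange(0.0, duration + sampling_interval / 2, sampling_interval)
    h = _gamma.pdf(t, a=peak_delay) - undershoot_ratio * _gamma.pdf(
        t, a=undershoot_delay
    )
    peak = np.max(np.abs(h))
    if peak == 0:
        raise ValueError("degenerate HRF: zero kernel")
    return h / peak


def _ar1_noise(n: int, phi: float, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) noise x_t = phi*x_{t-1} + eps_t, eps ~ N(0, sd^2)."""
    if sd == 0:
        return np.zeros(n)
    x = np.empty(n)
    # draw x_0 from the stationary distribution so the lag-1 autocorrelation
    # is phi from the first sample onwards
    x[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi * phi))
    eps = rng.normal(0.0, sd, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def simulate_subject(
    design: BlockDesign,
    params: BoldParams,
    seed: int,
    sampling_interval: float = 3.0,
) -> TimeSeries:
    """Simulate one subject's regional BOLD average for a block design.

    Deterministic: identical (design, params, seed) triples yield identical
    output.  The returned series has exactly one sample per design label.
    """
    if len(design) == 0:
        raise ValueError("design must be nonempty")
    n = len(design)
    amplitude = {
        "word": params.amplitude_word,
        "nonword": params.amplitude_nonword,
        "rest": 0.0,
    }
    boxcar = np.array([amplitude[lab] for lab in design.labels])
    hrf = double_gamma_hrf(
        sampling_interval,
        peak_delay=params.hrf_peak_delay,
        undershoot_delay=params.hrf_undershoot_delay,
        undershoot_ratio=params.hrf_undershoot_ratio,
    )
    response = np.convolve(boxcar, hrf)[:n]
    rng = np.random.default_rng(seed)
    noise = _ar1_noise(n, params.ar_coefficient, params.noise_sd, rng)
    return TimeSeries(
        params.baseline + response + noise, sampling_interval=sampling_interval
    )


def simulate_cohort(spec: CohortSpec) -> list[TimeSeries]:
    """Simulate ``n_subjects`` independent subjects.

    Per-subject seeds are derived as ``spec.seed + subject_index`` so runs
    are reproducible yet subjects are distinct.
    """
    design = make_design(spec.design)
    return [
        simulate_subject(
            design,
            spec.bold_params,
            seed=spec.seed + i,
            sampling_interval=spec.design.sampling_interval,
        )
        for i in range(spec.n_subjects)
    ]


def average_cohort(series_list: Sequence[TimeSeries]) -> TimeSeries:
    """Pointwise arithmetic mean of a cohort's series."""
    if not series_list:
        raise ValueError("cannot average an empty cohort")
    n = len(series_list[0])
    dt = series_list[0].sampling_interval
    for k, ts in enumerate(series_list):
        if len(ts) != n:
            raise ValueError(
                f"series {k} has length {len(ts)}, expected {n}: cohort "
                "members must have equal lengths"
            )
        if ts.sampling_interval != dt:
            raise ValueError("cohort members must share one sampling interval")
    stacked = np.stack([ts.values for ts in series_list])
    return TimeSeries(
        stacked.mean(axis=0),
        series_list[0].times.copy(),
        sampling_interval=dt,
    )
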