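"""Synthetic lateral-flow immunoassay (LFIA) scan traces with ground truth.

A fluorescence strip reader scans the nitrocellulose membrane and records a
512-point intensity trace.  A valid strip shows a control (C) peak in the
left half of the trace and, when analyte is present, a test (T) peak to its
right.  Real instruments additionally produce pure-noise scans, strips with a
missing C line, narrow interference spikes from membrane defects, baseline
drift and tailing peaks.  This module emulates all of those regimes so the
classifier/segmenter pipeline can be trained and evaluated without access to
proprietary instrument data.

Traces fall into four peak-shape classes:

    1 — noise (no valid peak; interference spikes allowed)
    2 — only C-peak
    3 — only T-peak
    4 — double peaks (C and T)

Each generated trace carries its class label, a binary mask of the C/T
integral regions (the segmentation target) and the generating peak
parameters.

Peaks are exponentially modified Gaussians (EMG): a Gaussian line shape
convolved with a one-sided exponential of time constant ``tau``, which
reduces to a pure Gaussian at ``tau = 0`` and produces the right-tailing
shapes seen on real strips for ``tau > 0``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.special import erfc, erfcx

TRACE_LENGTH = 512
#: zone boundaries: C peaks live in [0, 220], T peaks in [221, 511]
C_ZONE = (0, 220)
T_ZONE = (221, 511)
#: a peak's integral region is where its noiseless contribution exceeds
#: this fraction of its amplitude
MASK_THRESHOLD = 0.01

CLASS_NOISE = 1
CLASS_ONLY_C = 2
CLASS_ONLY_T = 3
CLASS_DOUBLE = 4


class SpecError(ValueError):
    """Raised for peak specifications outside the trace geometry."""


class InvalidClassError(ValueError):
    """Raised when an augmentation is applied to the wrong trace class."""


@dataclass(frozen=True)
class PeakSpec:
    """One peak in a synthetic trace.

    Parameters
    ----------
    center : int
        Index of the (pre-tailing) Gaussian center, in ``[0, 511]``.
    amplitude : float
        Height of the underlying Gaussian, intensity units, ``> 0``.
    sigma : float
        Gaussian width in samples, ``> 0``.
    tau : float
        Exponential tail constant in samples; ``0`` gives a symmetric
        Gaussian, larger values drag the peak to the right.
    zone : str
        ``"C"``, ``"T"`` or ``"INTERFERENCE"``.  Interference peaks render
        into the trace but never contribute to the ground-truth mask.
    """

    center: int
    amplitude: float
    sigma: float
    tau: float = 0.0
    zone: str = "C"

    def __post_init__(self) -> None:
        if not (0 <= self.center <= TRACE_LENGTH - 1):
            raise SpecError(f"peak center {self.center} outside [0, {TRACE_LENGTH - 1}]")
        if self.amplitude <= 0:
            raise SpecError("peak amplitude must be positive")
        if self.sigma <= 0:
            raise SpecError("peak sigma must be positive")
        if self.tau < 0:
            raise SpecError("peak tau must be nonnegative")
        if self.zone not in ("C", "T", "INTERFERENCE"):
            raise SpecError(f"unknown zone {self.zone!r}")


@dataclass(frozen=True)
class BaselineSpec:
    """Additive background: quadratic drift plus white Gaussian noise."""

    offset: float = 0.0
    drift_slope: float = 0.0
    drift_curvature: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise SpecError("baseline offset must be nonnegative")
        if self.noise_sd < 0:
            raise SpecError("noise_sd must be nonnegative")


@dataclass
class LabeledTrace:
    """A 512-point trace with class label, integral-region mask and provenance."""

    values: np.ndarray
    label: int
    mask: np.ndarray
    specs: list[PeakSpec] = field(default_factory=list)
    baseline: BaselineSpec | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if self.values.shape != (TRACE_LENGTH,):
            raise ValueError(f"trace must have length {TRACE_LENGTH}")
        if self.mask.shape != (TRACE_LENGTH,):
            raise ValueError(f"mask must have length {TRACE_LENGTH}")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask entries must be 0/1")
        if self.label not in (1, 2, 3, 4):
            raise ValueError("label must be in {1,2,3,4}")
        if self.label == CLASS_NOISE and self.mask.any():
            raise ValueError("noise traces must have an all-zero mask")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults emulate the composition of the instrument dataset the pipeline
    targets: roughly 900 noise, 900 only-C, 900 only-T and 1,400 double-peak
    traces.  Intensity units are photodiode counts on a scale where a valid
    C peak rises well above 1,000 counts (so the classical C-height rule is
    meaningful) over a low background.

    Valid C peaks are wide (``sigma`` 8–16 samples); interference artifacts
    are narrow spikes (``sigma`` 1–3) of up to half the main peak height —
    distinguishable by shape, as on real strips, but indistinguishable to a
    pure local-maximum rule.  A ``weak_t_fraction`` of T-bearing traces draw
    their T peak height from only 3–10x the noise SD (the height of the
    rendered, possibly tailed, peak — so tailing does not push the effective
    signal-to-noise ratio below the stated floor), the hard weak-T regime.
    """

    counts: tuple[int, int, int, int] = (900, 900, 900, 1400)
    c_center_range: tuple[int, int] = (80, 180)
    t_center_range: tuple[int, int] = (280, 420)
    c_amplitude_range: tuple[float, float] = (2000.0, 20000.0)
    t_amplitude_range: tuple[float, float] = (300.0, 15000.0)
    sigma_range: tuple[float, float] = (8.0, 16.0)
    tau_max: float = 8.0
    tailing_fraction: float = 0.4
    weak_t_fraction: float = 0.15
    weak_t_snr_range: tuple[float, float] = (3.0, 10.0)
    interference_max_count: int = 2
    interference_sigma_range: tuple[float, float] = (1.0, 3.0)
    interference_rel_amplitude: tuple[float, float] = (0.05, 0.5)
    noise_spike_amplitude_range: tuple[float, float] = (300.0, 5000.0)
    offset_range: tuple[float, float] = (50.0, 400.0)
    drift_slope_range: tuple[float, float] = (-1.5, 1.5)
    drift_curvature_range: tuple[float, float] = (-0.003, 0.003)
    noise_sd_range: tuple[float, float] = (10.0, 30.0)
    #: when True, interference spikes are re-drawn until their own 1% support
    #: is disjoint from the C/T integral regions.  A spike superimposed on a
    #: faint line region makes the class label ambiguous even to a human
    #: annotator, so classification datasets enable this; segmentation
    #: datasets keep overlaps (they are the hard cases of interest).
    interference_avoid_mask: bool = False
    seed: int = 42

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts) or len(self.counts) != 4:
            raise ValueError("counts must be four nonnegative integers")
        lo, hi = self.c_center_range
        if not (C_ZONE[0] <= lo <= hi <= C_ZONE[1]):
            raise ValueError("C center range must lie inside the C zone")
        lo, hi = self.t_center_range
        if not (T_ZONE[0] <= lo <= hi <= T_ZONE[1]):
            raise ValueError("T center range must lie inside the T zone")


def _emg_profile(spec: PeakSpec, n: int = TRACE_LENGTH) -> np.ndarray:
    """Noiseless contribution of one peak over sample indices 0..n-1.

    For ``tau = 0`` this is ``A * exp(-(x-c)^2 / (2 sigma^2))``.  For
    ``tau > 0`` the Gaussian is convolved with ``exp(-t/tau)/tau`` (t >= 0),
    evaluated through the scaled complementary error function ``erfcx`` to
    stay finite for small ``tau``:

        h(x) = A * sigma*sqrt(pi/2)/tau * erfcx(b) * exp(-d^2/(2 sigma^2)),
        d = x - c,  b = sigma/(tau*sqrt(2)) - d/(sigma*sqrt(2)).
    """
    x = np.arange(n, dtype=np.float64)
    d = x - spec.center
    gauss = np.exp(-0.5 * (d / spec.sigma) ** 2)
    if spec.tau <= 1e-9:
        return spec.amplitude * gauss
    b = spec.sigma / (spec.tau * np.sqrt(2.0)) - d / (spec.sigma * np.sqrt(2.0))
    scale = spec.amplitude * spec.sigma * np.sqrt(np.pi / 2.0) / spec.tau
    out = np.empty_like(d)
    lead = b >= 0
    # leading side: erfcx form, exp(a)*erfc(b) = erfcx(b)*exp(-d^2/2sigma^2)
    out[lead] = scale * erfcx(b[lead]) * gauss[lead]
    # tail side (b < 0): the plain form is well conditioned there since
    # a = sigma^2/(2 tau^2) - d/tau < 0 while erfc(b) is in (1, 2)
    a = (spec.sigma / spec.tau) ** 2 / 2.0 - d[~lead] / spec.tau
    out[~lead] = scale * np.exp(a) * erfc(b[~lead])
    return out


def render_trace(
    specs: Sequence[PeakSpec],
    baseline: BaselineSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Render a 512-point trace: quadratic baseline + EMG peaks + noise."""
    x = np.arange(TRACE_LENGTH, dtype=np.float64)
    values = (
        baseline.offset
        + baseline.drift_slope * x
        + baseline.drift_curvature * x**2
    )
    for spec in specs:
        values += _emg_profile(spec)
    if baseline.noise_sd > 0:
        values += rng.normal(0.0, baseline.noise_sd, size=TRACE_LENGTH)
    return values


def truth_mask(specs: Sequence[PeakSpec]) -> np.ndarray:
    """Ground-truth integral-region mask for a set of peaks.

    A point is inside the mask when any C or T peak's noiseless contribution
    is at least ``MASK_THRESHOLD`` (1%) of that peak's amplitude.
    Interference peaks contribute nothing.
    """
    mask = np.zeros(TRACE_LENGTH, dtype=np.int8)
    for spec in specs:
        if spec.zone == "INTERFERENCE":
            continue
        profile = _emg_profile(spec)
        mask[profile >= MASK_THRESHOLD * spec.amplitude] = 1
    return mask


def mask_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of ones as half-open ``(start, end)`` intervals."""
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return []
    padded = np.concatenate(([False], m, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def _zone_of_run(run: tuple[int, int]) -> str:
    start, end = run
    return "C" if start <= C_ZONE[1] else "T"


def _sample_main_peak(cfg: SynthConfig, zone: str, rng: np.random.Generator,
                      noise_sd: float, weak: bool = False) -> PeakSpec:
    """Draw one C or T peak whose 1%-threshold support stays inside its zone."""
    lo, hi = cfg.c_center_range if zone == "C" else cfg.t_center_range
    zone_lo, zone_hi = C_ZONE if zone == "C" else T_ZONE
    for _ in range(200):
        center = int(rng.integers(lo, hi + 1))
        sigma = rng.uniform(*cfg.sigma_range)
        tau = rng.uniform(1.0, cfg.tau_max) if rng.random() < cfg.tailing_fraction else 0.0
        if weak:
            # target a rendered peak HEIGHT of snr * noise_sd; for tailed
            # peaks the EMG maximum is below the Gaussian amplitude, so
            # normalize by the unit-amplitude profile height
            snr = rng.uniform(*cfg.weak_t_snr_range)
            unit = PeakSpec(center=center, amplitude=1.0, sigma=sigma, tau=tau,
                            zone=zone)
            amplitude = snr * noise_sd / float(_emg_profile(unit).max())
        elif zone == "C":
            amplitude = np.exp(rng.uniform(*np.log(cfg.c_amplitude_range)))
        else:
            amplitude = np.exp(rng.uniform(*np.log(cfg.t_amplitude_range)))
        spec = PeakSpec(center=center, amplitude=amplitude, sigma=sigma, tau=tau, zone=zone)
        runs = mask_runs(truth_mask([spec]))
        if len(runs) == 1 and zone_lo <= runs[0][0] and runs[0][1] - 1 <= zone_hi:
            return spec
    raise RuntimeError("could not sample a zone-contained peak; check config ranges")


def _sample_interference(cfg: SynthConfig, rng: np.random.Generator,
                         ref_amplitude: float,
                         occupied: np.ndarray | None = None) -> PeakSpec:
    for _ in range(100):
        center = int(rng.integers(5, TRACE_LENGTH - 5))
        sigma = rng.uniform(*cfg.interference_sigma_range)
        amplitude = ref_amplitude * rng.uniform(*cfg.interference_rel_amplitude)
        spec = PeakSpec(center=center, amplitude=amplitude, sigma=sigma, tau=0.0,
                        zone="INTERFERENCE")
        if occupied is None:
            return spec
        support = _emg_profile(spec) >= MASK_THRESHOLD * spec.amplitude
        if not (support & occupied).any():
            return spec
    raise RuntimeError("could not place an interference spike off the mask")


def _sample_baseline(cfg: SynthConfig, rng: np.random.Generator) -> BaselineSpec:
    return BaselineSpec(
        offset=rng.uniform(*cfg.offset_range),
        drift_slope=rng.uniform(*cfg.drift_slope_range),
        drift_curvature=rng.uniform(*cfg.drift_curvature_range),
        noise_sd=rng.uniform(*cfg.noise_sd_range),
    )


def _make_trace(cfg: SynthConfig, label: int, rng: np.random.Generator) -> LabeledTrace:
    baseline = _sample_baseline(cfg, rng)
    specs: list[PeakSpec] = []
    if label in (CLASS_ONLY_C, CLASS_DOUBLE):
        specs.append(_sample_main_peak(cfg, "C", rng, baseline.noise_sd))
    if label in (CLASS_ONLY_T, CLASS_DOUBLE):
        weak = rng.random() < cfg.weak_t_fraction
        specs.append(_sample_main_peak(cfg, "T", rng, baseline.noise_sd, weak=weak))

    if label == CLASS_NOISE:
        # spikes only; absolute amplitudes so some exceed the classical
        # 1,000-count C-height rule and fool the rule-based baselines
        n_spikes = int(rng.integers(1, cfg.interference_max_count + 2))
        for _ in range(n_spikes):
            amp = rng.uniform(*cfg.noise_spike_amplitude_range)
            specs.append(PeakSpec(
                center=int(rng.integers(5, TRACE_LENGTH - 5)),
                amplitude=amp,
                sigma=rng.uniform(*cfg.interference_sigma_range),
                tau=0.0, zone="INTERFERENCE"))
    else:
        ref = max(s.amplitude for s in specs)
        occupied = truth_mask(specs).astype(bool) if cfg.interference_avoid_mask else None
        for _ in range(int(rng.integers(0, cfg.interference_max_count + 1))):
            specs.append(_sample_interference(cfg, rng, ref, occupied))

    values = render_trace(specs, baseline, rng)
    mask = truth_mask(specs)
    return LabeledTrace(values=values, label=label, mask=mask,
                        specs=specs, baseline=baseline)


def generate_dataset(config: SynthConfig | None = None) -> list[LabeledTrace]:
    """Generate the configured number of traces per class, reproducibly.

    Traces are generated class by class (all class 1, then 2, 3, 4), each
    drawn from a single NumPy generator seeded with ``config.seed``, so the
    same config always yields a bitwise-identical dataset.
    """
    cfg = config or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    dataset: list[LabeledTrace] = []
    for label, count in zip((1, 2, 3, 4), cfg.counts):
        for _ in range(count):
            dataset.append(_make_trace(cfg, label, rng))
    return dataset


def remove_c_peak(trace: LabeledTrace) -> LabeledTrace:
    """Turn a double-peak trace into an only-T trace by spline infill.

    The C integral region is replaced with a cubic spline fitted through the
    flanking background samples, emulating strips whose control line failed
    to develop; the T region and everything else are untouched.  This is the
    augmentation used to mass-produce class-3 training data.
    """
    if trace.label != CLASS_DOUBLE:
        raise InvalidClassError("remove_c_peak requires a class-4 (double-peak) trace")
    runs = mask_runs(trace.mask)
    c_runs = [r for r in runs if _zone_of_run(r) == "C"]
    if not c_runs:
        raise InvalidClassError("no C region found in mask")
    start, end = c_runs[0]

    # flanking knots skip a guard gap: just outside the 1%-threshold run the
    # peak still contributes ~1% of its amplitude, which would bow the spline
    gap, n_flank = 16, 16
    in_any_run = trace.mask.astype(bool)
    left = np.arange(max(0, start - gap - n_flank), max(0, start - gap))
    right = np.arange(min(TRACE_LENGTH, end + gap),
                      min(TRACE_LENGTH, end + gap + n_flank))
    knots = np.concatenate([left, right])
    knots = knots[~in_any_run[knots]]
    spline = CubicSpline(knots, trace.values[knots])

    values = trace.values.copy()
    inside = np.arange(start, end)
    values[inside] = spline(inside)
    mask = trace.mask.copy()
    mask[inside] = 0
    specs = [s for s in trace.specs if s.zone != "C"]
    return LabeledTrace(values=values, label=CLASS_ONLY_T, mask=mask,
                        specs=specs, baseline=trace.baseline)


# ---------------------------------------------------------------------------
# dataset I/O: plain CSV per split plus a JSON provenance sidecar


def save_dataset(dataset: Sequence[LabeledTrace], out_dir: str | Path,
                 name: str = "traces", config: SynthConfig | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    values = pd.DataFrame(
        np.stack([t.values for t in dataset]),
        columns=[f"v{i}" for i in range(TRACE_LENGTH)],
    )
    values.insert(0, "label", [t.label for t in dataset])
    values.insert(0, "trace_id", np.arange(len(dataset)))
    values.to_csv(out / f"{name}.csv", index=False)

    masks = pd.DataFrame(
        np.stack([t.mask for t in dataset]),
        columns=[f"m{i}" for i in range(TRACE_LENGTH)],
    )
    masks.insert(0, "trace_id", np.arange(len(dataset)))
    masks.to_csv(out / f"{name}_masks.csv", index=False)

    if config is not None:
        with open(out / f"{name}_config.json", "w") as fh:
            json.dump(dataclasses.asdict(config), fh, indent=2)


def load_dataset(out_dir: str | Path, name: str = "traces") -> list[LabeledTrace]:
    out = Path(out_dir)
    values = pd.read_csv(out / f"{name}.csv")
    masks = pd.read_csv(out / f"{name}_masks.csv")
    dataset = []
    vcols = [f"v{i}" for i in range(TRACE_LENGTH)]
    mcols = [f"m{i}" for i in range(TRACE_LENGTH)]
    for (_, vrow), (_, mrow) in zip(values.iterrows(), masks.iterrows()):
        dataset.append(LabeledTrace(
            values=vrow[vcols].to_numpy(dtype=np.float64),
            label=int(vrow["label"]),
            mask=mrow[mcols].to_numpy(dtype=np.int8),
        ))
    return dataset
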