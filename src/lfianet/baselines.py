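"""Classical peak-finding comparators.

Two traditional detectors stand against the deep pipeline:

* **direct peak location** — all strict local maxima filtered by prominence
  (SciPy ``find_peaks``);
* **CWT ridge detection** — peaks as ridge lines of the continuous wavelet
  transform under a Ricker wavelet (SciPy ``find_peaks_cwt``).

Either detector's peaks are then pushed through the same four rule-based
post-processing steps used on real strip readers:

1. split the 512 samples into a C zone (indices 0–220) and a T zone
   (221–511);
2. the tallest local maximum in the C zone is the C-peak candidate; it is a
   valid C peak only if its height exceeds 1,000 counts;
3. the tallest local maximum in the T zone is the T-peak candidate;
4. classify: neither peak -> class 1 (noise), C only -> class 2, T only ->
   class 3, both -> class 4.

Integral regions for detected peaks come from ``peak_widths`` evaluated
just above the prominence base (relative height 0.99, i.e. where the signal
has dropped to 1% of the prominence), clipped to the peak's zone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .synthdata import C_ZONE, T_ZONE, TRACE_LENGTH

try:  # private scipy location; fall back to the base class if it moves
    from scipy.signal._peak_finding_utils import PeakPropertyWarning
except ImportError:  # pragma: no cover
    PeakPropertyWarning = RuntimeWarning

#: classical validity threshold on the C-peak height, in raw counts
C_HEIGHT_THRESHOLD = 1000.0
DEFAULT_MIN_PROMINENCE = 200.0
DEFAULT_CWT_WIDTHS = np.arange(1, 33)
DEFAULT_CWT_MIN_SNR = 4.0


@dataclass(frozen=True)
class DetectedPeak:
    index: int
    height: float
    prominence: float
    left_base: int
    right_base: int

    def __post_init__(self) -> None:
        if not (self.left_base <= self.index <= self.right_base):
            raise ValueError("peak bases must bracket the peak index")


@dataclass(frozen=True)
class RuleResult:
    label: int
    c_peak: DetectedPeak | None = None
    t_peak: DetectedPeak | None = None
    c_region: tuple[int, int] | None = None
    t_region: tuple[int, int] | None = None


def direct_peak_locate(trace: np.ndarray,
                       min_prominence: float = DEFAULT_MIN_PROMINENCE) -> list[DetectedPeak]:
    """All local maxima with prominence >= ``min_prominence``."""
    x = _check_trace(trace)
    idx, props = signal.find_peaks(x, prominence=min_prominence)
    return [
        DetectedPeak(index=int(i), height=float(x[i]),
                     prominence=float(p),
                     left_base=int(lb), right_base=int(rb))
        for i, p, lb, rb in zip(idx, props["prominences"],
                                props["left_bases"], props["right_bases"])
    ]


def cwt_peak_locate(trace: np.ndarray,
                    widths: np.ndarray = DEFAULT_CWT_WIDTHS,
                    min_snr: float = DEFAULT_CWT_MIN_SNR) -> list[DetectedPeak]:
    """Peaks from CWT ridge lines, with heights/prominences read off the trace.

    ``find_peaks_cwt`` returns ridge positions only; each is snapped to the
    nearest local maximum within +-5 samples before prominences are computed,
    since a ridge position on a noisy trace need not be a strict local
    maximum.
    """
    x = _check_trace(trace)
    widths = np.asarray(widths)
    if widths.size == 0 or np.any(np.diff(widths) <= 0):
        raise ValueError("widths must be nonempty and increasing")
    idx = signal.find_peaks_cwt(x, widths, min_snr=min_snr)
    if len(idx) == 0:
        return []
    snapped = sorted({_snap_to_local_max(x, int(i)) for i in idx})
    snapped = [i for i in snapped if 0 < i < len(x) - 1]
    if not snapped:
        return []
    with warnings.catch_warnings():
        # a snapped ridge on a monotone stretch has prominence 0; such
        # pseudo-peaks are dropped below rather than warned about
        warnings.simplefilter("ignore", PeakPropertyWarning)
        proms, left, right = signal.peak_prominences(x, snapped)
    return [
        DetectedPeak(index=int(i), height=float(x[i]), prominence=float(p),
                     left_base=int(lb), right_base=int(rb))
        for i, p, lb, rb in zip(snapped, proms, left, right)
        if p > 0
    ]


def _snap_to_local_max(x: np.ndarray, i: int, radius: int = 5) -> int:
    lo = max(1, i - radius)
    hi = min(len(x) - 1, i + radius + 1)
    return lo + int(np.argmax(x[lo:hi]))


def rule_classify(peaks: list[DetectedPeak], trace: np.ndarray) -> RuleResult:
    """Apply the four classical post-processing steps to located peaks."""
    _check_trace(trace)
    c_cands = [p for p in peaks if C_ZONE[0] <= p.index <= C_ZONE[1]]
    t_cands = [p for p in peaks if T_ZONE[0] <= p.index <= T_ZONE[1]]
    c_peak = max(c_cands, key=lambda p: p.height, default=None)
    if c_peak is not None and c_peak.height <= C_HEIGHT_THRESHOLD:
        c_peak = None
    t_peak = max(t_cands, key=lambda p: p.height, default=None)
    label = {(False, False): 1, (True, False): 2,
             (False, True): 3, (True, True): 4}[(c_peak is not None, t_peak is not None)]
    return RuleResult(label=label, c_peak=c_peak, t_peak=t_peak)


def rule_regions(trace: np.ndarray, result: RuleResult) -> RuleResult:
    """Attach width-at-base integral regions for whichever peaks are present."""
    x = _check_trace(trace)
    c_region = _peak_region(x, result.c_peak, C_ZONE) if result.c_peak else None
    t_region = _peak_region(x, result.t_peak, T_ZONE) if result.t_peak else None
    return RuleResult(label=result.label, c_peak=result.c_peak, t_peak=result.t_peak,
                      c_region=c_region, t_region=t_region)


def analyze_with_rules(trace: np.ndarray, method: str = "direct",
                       **kwargs) -> RuleResult:
    """Locate peaks with the chosen method, classify, and attach regions."""
    if method == "direct":
        peaks = direct_peak_locate(trace, **kwargs)
    elif method == "cwt":
        peaks = cwt_peak_locate(trace, **kwargs)
    else:
        raise ValueError("method must be 'direct' or 'cwt'")
    return rule_regions(trace, rule_classify(peaks, trace))


def regions_to_mask(result: RuleResult) -> np.ndarray:
    """Binary 512-mask built from the rule-based integral regions."""
    mask = np.zeros(TRACE_LENGTH, dtype=np.int8)
    for region in (result.c_region, result.t_region):
        if region is not None:
            mask[region[0]:region[1]] = 1
    return mask


#: width evaluation height as a fraction of prominence below the peak: 0.99
#: means the region ends where the signal has dropped to 1% of the peak's
#: prominence, covering essentially the full peak support.  Exactly 1.0 (the
#: prominence base) degenerates on clean traces, where the base is only
#: reached at the trace ends.
REGION_REL_HEIGHT = 0.99


def _peak_region(x: np.ndarray, peak: DetectedPeak,
                 zone: tuple[int, int]) -> tuple[int, int]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PeakPropertyWarning)
        widths, _, left_ip, right_ip = signal.peak_widths(
            x, [peak.index], rel_height=REGION_REL_HEIGHT)
    start = int(np.floor(left_ip[0]))
    end = int(np.ceil(right_ip[0])) + 1
    start = max(start, zone[0])
    end = min(end, zone[1] + 1)
    return (start, end)


def _check_trace(trace: np.ndarray) -> np.ndarray:
    x = np.asarray(trace, dtype=np.float64)
    if x.shape != (TRACE_LENGTH,):
        raise ValueError(f"expected a trace of length {TRACE_LENGTH}")
    return x
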