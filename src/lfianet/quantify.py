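"""From segmentation masks to analyte concentrations.

The sandwich-format strip produces a control (C) line and a test (T) line
whose fluorescence is proportional to analyte concentration.  Quantification
proceeds: threshold the segmenter's probability mask, keep the largest run
per zone as the C and T integral regions, integrate background-subtracted
intensity over each region, form the T/C area ratio, and map T/C to
concentration through a four-parameter logistic (4PL) standard curve

    y = d + (a - d) / (1 + (x / c)^b)

with ``a`` the response at zero concentration, ``d`` the response at
infinite concentration, ``c`` the inflection concentration and ``b`` the
slope factor.  Assay precision is summarized by the coefficient of
variation (CV) and trueness by the recovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .models import PeakClassifier, UNetSegmenter, classify, segment
from .preprocess import to_model_input
from .synthdata import C_ZONE, T_ZONE, TRACE_LENGTH, mask_runs


class InvalidAssayError(ValueError):
    """Raised when a quantity cannot be computed from the assay data."""


class FitError(RuntimeError):
    """Raised when the 4PL fit fails to converge."""


@dataclass(frozen=True)
class PeakRegion:
    """Half-open index interval of one integral region."""

    start: int
    end: int
    zone: str
    area: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end <= TRACE_LENGTH):
            raise ValueError("region must be a nonempty interval within the trace")
        if self.zone not in ("C", "T"):
            raise ValueError("zone must be 'C' or 'T'")


@dataclass(frozen=True)
class FourPLCurve:
    a: float  # response at zero concentration
    b: float  # slope factor
    c: float  # inflection concentration
    d: float  # response at infinite concentration
    r_squared: float = float("nan")

    def __call__(self, x):
        x = np.asarray(x, dtype=np.float64)
        return self.d + (self.a - self.d) / (1.0 + (x / self.c) ** self.b)


@dataclass(frozen=True)
class AssayResult:
    label: int
    valid: bool
    t_over_c: float | None = None
    concentration: float | None = None
    c_region: PeakRegion | None = None
    t_region: PeakRegion | None = None
    reason: str = ""


def mask_to_regions(prob: np.ndarray, cutoff: float = 0.6) -> list[PeakRegion]:
    """Binarize at ``cutoff`` and keep the largest run per zone.

    The longest run intersecting the C zone becomes the C region; the
    longest run intersecting the T zone becomes the T region; all other
    runs are discarded.  Ties go to the leftmost run.
    """
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must be in (0, 1)")
    prob = np.asarray(prob, dtype=np.float64)
    binary = (prob >= cutoff).astype(np.int8)
    runs = mask_runs(binary)
    regions: list[PeakRegion] = []
    for zone, (lo, hi) in (("C", C_ZONE), ("T", T_ZONE)):
        candidates = [r for r in runs if r[0] <= hi and r[1] - 1 >= lo]
        if candidates:
            start, end = max(candidates, key=lambda r: (r[1] - r[0], -r[0]))
            regions.append(PeakRegion(start=start, end=end, zone=zone))
    # a run spanning both zones would be claimed twice; keep its first claim
    seen: set[tuple[int, int]] = set()
    unique = []
    for r in regions:
        if (r.start, r.end) not in seen:
            seen.add((r.start, r.end))
            unique.append(r)
    return unique


def integrate_region(trace: np.ndarray, region: PeakRegion | None) -> float:
    """Background-subtracted area: sum of ``value - trace_min`` over the region.

    The background is the trace minimum (the same notion the preprocessing
    uses); pointwise contributions are clamped at zero.
    """
    if region is None:
        return 0.0
    x = np.asarray(trace, dtype=np.float64)
    if x.shape != (TRACE_LENGTH,):
        raise ValueError(f"expected a trace of length {TRACE_LENGTH}")
    segment_vals = x[region.start:region.end] - x.min()
    return float(np.clip(segment_vals, 0.0, None).sum())


def t_over_c(c_area: float, t_area: float) -> float:
    """T/C area ratio, the normalized assay response."""
    if c_area <= 0:
        raise InvalidAssayError("C-peak area must be positive (invalid strip)")
    return t_area / c_area


def _4pl(x, a, b, c, d):
    return d + (a - d) / (1.0 + (x / c) ** b)


def fit_4pl(concentrations: np.ndarray, responses: np.ndarray) -> FourPLCurve:
    """Least-squares 4PL fit of response against concentration.

    Zero-concentration calibrators are handled exactly through the ``a``
    asymptote (``(0/c)^b = 0`` for positive ``b``).
    """
    x = np.asarray(concentrations, dtype=np.float64)
    y = np.asarray(responses, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("concentrations and responses must be 1D and equal length")
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    pos = x > 0
    p0 = (float(y[np.argmin(x)]), 1.0, float(np.median(x[pos])), float(y[np.argmax(x)]))
    try:
        popt, _ = curve_fit(_4pl, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - exercised only on bad data
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    a, b, c, d = (float(v) for v in popt)
    resid = y - _4pl(x, *popt)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return FourPLCurve(a=a, b=b, c=c, d=d, r_squared=r2)


def inverse_4pl(curve: FourPLCurve, response: float) -> float:
    """Concentration for a response: ``x = c ((a - y)/(y - d))^(1/b)``.

    A response equal to ``a`` maps to concentration 0 exactly; responses
    outside the open interval between the asymptotes are out of range.
    """
    y = float(response)
    lo, hi = sorted((curve.a, curve.d))
    if y == curve.a:
        return 0.0
    if not (lo < y < hi):
        raise InvalidAssayError(
            f"response {y} outside the curve's range ({lo}, {hi})")
    return float(curve.c * ((curve.a - y) / (y - curve.d)) ** (1.0 / curve.b))


def percent_cv(values: np.ndarray) -> float:
    """Coefficient of variation, percent: ``100 * SD / mean`` with the sample
    (ddof=1) standard deviation.  Round only for presentation."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least two replicates")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("mean must be positive")
    return float(100.0 * v.std(ddof=1) / mean)


def cv_from_summary(mean: float, sd: float) -> float:
    """CV from a reported mean and SD (as printed in assay tables)."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    return 100.0 * sd / mean


def percent_recovery(measured_mean: float, nominal: float) -> float:
    """Recovery rate, percent: ``100 * measured / nominal``."""
    if nominal <= 0:
        raise ValueError("nominal concentration must be positive")
    return 100.0 * measured_mean / nominal


def analyze_trace(
    trace: np.ndarray,
    classifier: PeakClassifier,
    segmenter: UNetSegmenter,
    curve: FourPLCurve | None = None,
    cutoff: float = 0.6,
) -> AssayResult:
    """Full pipeline on one raw trace: classify, segment if double-peaked,
    integrate, and convert T/C to concentration if a curve is given.

    Class 1 (noise) and class 3 (no control line) are invalid assays.
    Class 2 (only C) is a valid zero: T/C = 0.  Class 4 runs through the
    segmenter; if thresholding fails to produce both regions the result is
    invalid with a reason code.
    """
    x = np.asarray(trace, dtype=np.float64)
    inp = to_model_input(x)
    label = int(classify(classifier, inp).argmax(axis=1)[0]) + 1
    if label in (1, 3):
        return AssayResult(label=label, valid=False,
                           reason="no valid control line" if label == 3 else "noise trace")
    if label == 2:
        conc = 0.0 if curve is not None else None
        return AssayResult(label=2, valid=True, t_over_c=0.0, concentration=conc)

    prob = segment(segmenter, inp)[0]
    regions = {r.zone: r for r in mask_to_regions(prob, cutoff)}
    if "C" not in regions or "T" not in regions:
        missing = "C" if "C" not in regions else "T"
        return AssayResult(label=4, valid=False,
                           reason=f"segmentation produced no {missing} region")
    c_reg = regions["C"]
    t_reg = regions["T"]
    c_area = integrate_region(x, c_reg)
    t_area = integrate_region(x, t_reg)
    if c_area <= 0:
        return AssayResult(label=4, valid=False, reason="zero C-peak area")
    ratio = t_over_c(c_area, t_area)
    c_reg = PeakRegion(c_reg.start, c_reg.end, "C", c_area)
    t_reg = PeakRegion(t_reg.start, t_reg.end, "T", t_area)
    conc: float | None = None
    if curve is not None:
        try:
            conc = inverse_4pl(curve, ratio)
        except InvalidAssayError:
            lo, hi = sorted((curve.a, curve.d))
            # clamp responses beyond the upper asymptote is not meaningful;
            # report invalid instead of extrapolating
            return AssayResult(label=4, valid=False, t_over_c=ratio,
                               c_region=c_reg, t_region=t_reg,
                               reason="T/C outside the standard curve range")
    return AssayResult(label=4, valid=True, t_over_c=ratio, concentration=conc,
                       c_region=c_reg, t_region=t_reg)
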