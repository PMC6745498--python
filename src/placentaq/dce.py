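"""Signal-intensity dynamics of contrast-enhanced placental MRI.

A placenta imaged repeatedly after injection of a macromolecular contrast
agent shows a biphasic mean-signal-intensity (SI) curve: an initial
enhancement as the agent perfuses and is internalized by the labyrinth
trophoblasts, a decline, and a late recovery as the agent is recycled to
the maternal circulation. Two dimensionless landmark statistics summarize
a curve:

* **initial enhancement** ``E`` — SI at the first local maximum divided by
  the initial SI;
* **recovery** ``R`` — SI at the second local maximum divided by the SI at
  the local minimum lying between the two maxima.

A third quantity, the rate of enhancement (**ROE**, min⁻¹), is the
per-interval rate of SI change scaled to the vena cava signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    LandmarkError,
    NoFirstMaximum,
    NoRecoveryLimb,
    PipelineError,
)

__all__ = [
    "SICurve",
    "Landmarks",
    "DynamicsResult",
    "extract_roi_timeseries",
    "detect_landmarks",
    "initial_enhancement",
    "recovery",
    "compute_roe",
    "analyze_curve",
    "analyze_cohort",
    "CohortResult",
]


@dataclass(frozen=True)
class SICurve:
    """Mean signal intensity of one region of interest over time.

    Parameters
    ----------
    times:
        Acquisition timepoints in seconds, strictly increasing.
    values:
        Mean SI per timepoint, arbitrary non-negative scanner units.
    id:
        Placenta (or vessel) identifier.
    group:
        Genotype / condition label.
    """

    times: np.ndarray
    values: np.ndarray
    id: str = "roi"
    group: str = "NA"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or times.size != values.size:
            raise DataError("times and values must be 1-D arrays of equal length")
        if times.size < 3:
            raise DataError(f"curve {self.id!r}: need >= 3 timepoints, got {times.size}")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(values)):
            raise DataError(f"curve {self.id!r}: non-finite entries")
        if np.any(np.diff(times) <= 0):
            raise DataError(f"curve {self.id!r}: times must be strictly increasing")
        if np.any(values < 0):
            raise DataError(f"curve {self.id!r}: negative signal intensity")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class Landmarks:
    """Indices of the three SI landmarks on a curve's original time axis."""

    first_max_index: int
    interior_min_index: int
    second_max_index: int

    def __post_init__(self) -> None:
        if not 0 < self.first_max_index < self.interior_min_index < self.second_max_index:
            raise DataError(
                "landmark ordering violated: need 0 < first max < interior min < second max"
            )


@dataclass(frozen=True)
class DynamicsResult:
    """Landmark statistics of one SI curve."""

    initial_enhancement: float
    recovery: float
    landmarks: Landmarks
    roe: np.ndarray | None = field(default=None, compare=False)


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge reflection; output length preserved."""
    if window == 1:
        return values.astype(float)
    half = window // 2
    padded = np.pad(values.astype(float), half, mode="edge")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def extract_roi_timeseries(
    volumes: np.ndarray,
    masks: np.ndarray,
    times_s: np.ndarray,
    id: str = "roi",
    group: str = "NA",
) -> SICurve:
    """Average the voxels inside a region of interest at every timepoint.

    Parameters
    ----------
    volumes:
        Array of shape ``(T, ...)`` — one spatial volume (or image) per
        timepoint.
    masks:
        Boolean array, either one mask of the spatial shape (reused at every
        timepoint — the case without fetal motion) or ``(T, ...)`` with one
        mask per timepoint (manually re-marked regions).
    times_s:
        Acquisition times in seconds, length ``T``.
    """
    volumes = np.asarray(volumes, dtype=float)
    masks = np.asarray(masks, dtype=bool)
    n_t = volumes.shape[0]
    spatial = volumes.shape[1:]
    if masks.shape == spatial:
        masks = np.broadcast_to(masks, (n_t, *spatial))
    elif masks.shape != (n_t, *spatial):
        raise DataError(
            f"mask shape {masks.shape} matches neither one volume {spatial} "
            f"nor the full series {(n_t, *spatial)}"
        )
    times_s = np.asarray(times_s, dtype=float)
    if times_s.shape != (n_t,):
        raise DataError(f"need {n_t} timepoints, got {times_s.shape}")
    values = np.empty(n_t)
    for k in range(n_t):
        inside = masks[k]
        if not inside.any():
            raise DataError(f"empty ROI mask at timepoint {k}")
        values[k] = volumes[k][inside].mean()
    return SICurve(times=times_s, values=values, id=id, group=group)


def detect_landmarks(curve: SICurve, smooth_window: int = 3) -> Landmarks:
    """Locate first maximum, interior minimum, and second maximum.

    The search runs on a moving-average-smoothed copy of the series (window
    ``smooth_window``, odd); each index is then mapped back to the original
    axis by snapping to the raw-series extremum within the smoothing
    half-window, and the ratio statistics are always read from the
    *unsmoothed* values. Without the snap, the phase lag a moving average
    imposes on an asymmetric peak would systematically bias the ratios.

    The first maximum is the earliest interior point that is a non-strict
    local maximum exceeding the initial SI. The interior minimum is the
    global minimum after it (earliest tie); if it falls on the final
    timepoint there is no recovery limb. The second maximum is the maximum
    after the interior minimum — the final timepoint is eligible because
    recovery may still be rising when acquisition stops.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise DataError(f"smooth_window must be odd and >= 1, got {smooth_window}")
    n = len(curve)
    if n < 5:
        raise DataError(f"curve {curve.id!r}: need >= 5 timepoints for landmark detection")
    s = _moving_average(curve.values, smooth_window)

    first_max = None
    for i in range(1, n - 1):
        if s[i] >= s[i - 1] and s[i] >= s[i + 1] and s[i] > s[0]:
            first_max = i
            break
    if first_max is None:
        raise NoFirstMaximum(
            f"curve {curve.id!r}: no interior maximum exceeding the initial SI"
        )

    interior_min = first_max + 1 + int(np.argmin(s[first_max + 1 :]))
    if interior_min == n - 1:
        raise NoRecoveryLimb(
            f"curve {curve.id!r}: interior minimum at the final timepoint"
        )
    second_max = interior_min + 1 + int(np.argmax(s[interior_min + 1 :]))

    half = smooth_window // 2
    raw = curve.values

    def snap(index: int, lo: int, hi: int, extremum) -> int:
        lo, hi = max(lo, index - half), min(hi, index + half)
        return lo + int(extremum(raw[lo : hi + 1]))

    first_max = snap(first_max, 1, n - 2, np.argmax)
    interior_min = snap(interior_min, first_max + 1, n - 2, np.argmin)
    second_max = snap(second_max, interior_min + 1, n - 1, np.argmax)
    return Landmarks(first_max, interior_min, second_max)


def initial_enhancement(curve: SICurve, landmarks: Landmarks) -> float:
    """Ratio of the SI at the first local maximum to the initial SI."""
    baseline = curve.values[0]
    if baseline == 0:
        raise DataError(f"curve {curve.id!r}: initial SI is zero")
    return float(curve.values[landmarks.first_max_index] / baseline)


def recovery(curve: SICurve, landmarks: Landmarks) -> float:
    """Ratio of the SI at the second maximum to the SI at the interior minimum."""
    trough = curve.values[landmarks.interior_min_index]
    if trough == 0:
        raise DataError(f"curve {curve.id!r}: SI at the interior minimum is zero")
    return float(curve.values[landmarks.second_max_index] / trough)


def vena_cava_reference(vena_cava: SICurve) -> float:
    """Scalar vena cava concentration surrogate: mean of the three timepoints
    immediately after the vena cava SI peak (the early plateau). Falls back
    to the peak value itself when the peak is terminal."""
    peak = int(np.argmax(vena_cava.values))
    plateau = vena_cava.values[peak + 1 : peak + 4]
    if plateau.size == 0:
        plateau = vena_cava.values[peak : peak + 1]
    return float(plateau.mean())


def compute_roe(curve: SICurve, vena_cava: SICurve) -> np.ndarray:
    """Rate of enhancement per scan interval, in min⁻¹.

    ``ROE_k = (SI_{k+1} - SI_k) / Δt_k[min] / C_vc`` where ``C_vc`` is the
    vena cava plateau reference (see :func:`vena_cava_reference`).
    """
    if len(curve) != len(vena_cava) or not np.allclose(curve.times, vena_cava.times):
        raise DataError("placental and vena cava curves are on different schedules")
    c_vc = vena_cava_reference(vena_cava)
    if c_vc <= 0:
        raise DataError("vena cava reference level is not positive")
    dt_min = np.diff(curve.times) / 60.0
    return np.diff(curve.values) / dt_min / c_vc


def analyze_curve(
    curve: SICurve,
    smooth_window: int = 3,
    vena_cava: SICurve | None = None,
) -> DynamicsResult:
    """Full landmark analysis of one curve (ROE only if a vena cava curve is given)."""
    lm = detect_landmarks(curve, smooth_window=smooth_window)
    roe = compute_roe(curve, vena_cava) if vena_cava is not None else None
    return DynamicsResult(
        initial_enhancement=initial_enhancement(curve, lm),
        recovery=recovery(curve, lm),
        landmarks=lm,
        roe=roe,
    )


@dataclass(frozen=True)
class CohortResult:
    """Per-curve landmark statistics, per-group summary, and failures."""

    table: pd.DataFrame
    summary: pd.DataFrame
    failures: pd.DataFrame


def analyze_cohort(
    curves: list[SICurve],
    smooth_window: int = 3,
    vena_cava: SICurve | None = None,
) -> CohortResult:
    """Analyze a cohort of curves; landmark failures are recorded, not raised.

    Per-group summary reports mean and SEM of both ratios, matching the
    means + SEM convention of the source assays.
    """
    if not curves:
        raise DataError("empty cohort")
    rows, failures = [], []
    for curve in curves:
        try:
            res = analyze_curve(curve, smooth_window=smooth_window, vena_cava=vena_cava)
        except LandmarkError as exc:
            failures.append(
                {"id": curve.id, "group": curve.group, "reason": type(exc).__name__,
                 "detail": str(exc)}
            )
            continue
        lm = res.landmarks
        rows.append(
            {
                "id": curve.id,
                "group": curve.group,
                "first_max_s": curve.times[lm.first_max_index],
                "min_s": curve.times[lm.interior_min_index],
                "second_max_s": curve.times[lm.second_max_index],
                "initial_enhancement": res.initial_enhancement,
                "recovery": res.recovery,
            }
        )
    if not rows:
        raise PipelineError("landmark detection failed for every curve in the cohort")
    table = pd.DataFrame(rows)
    summary = (
        table.groupby("group", sort=True)
        .agg(
            n=("id", "size"),
            mean_initial_enhancement=("initial_enhancement", "mean"),
            sem_initial_enhancement=("initial_enhancement", "sem"),
            mean_recovery=("recovery", "mean"),
            sem_recovery=("recovery", "sem"),
        )
        .fillna({"sem_initial_enhancement": 0.0, "sem_recovery": 0.0})
        .reset_index()
    )
    fail_df = pd.DataFrame(failures, columns=["id", "group", "reason", "detail"])
    return CohortResult(table=table, summary=summary, failures=fail_df)
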