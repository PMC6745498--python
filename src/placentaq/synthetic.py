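"""Synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: biphasic
placental signal-intensity curves with genotype-dependent amplitudes,
counting fields of syncytia with Bernoulli nucleus positivity, staining
images with a planted positive-area fraction, and expression matrices
with planted between-group fold changes. All generators are pure
functions of their parameters and an integer seed.

The noiseless curve model is

    S(t) = S0 * (1 + A1 * g(t; t1) + A2 * h(t; onset, rate))

where ``g(t) = (t/t1)**3 * exp(3*(1 - t/t1))`` is a gamma-variate uptake
pulse peaking at ``t1`` with unit height (shape 3, so the uptake washes
out by mid-window), and ``h`` is a logistic rise centred at ``onset``
with steepness ``rate``. This guarantees exactly one early maximum
followed by a decline and a delayed recovery — the qualitative shape of
macromolecular contrast dynamics in the placental labyrinth,
where agent uptake by syncytiotrophoblasts is followed by recycling into
the maternal circulation. Ground-truth landmark ratios are evaluated by
brute force on a dense time grid, not in closed form, so they stay valid
if the curve family changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .dce import SICurve
from .errors import ConfigError
from .histo import IntensityImage, SyncytiaField
from .stats import ExpressionMatrix

import pandas as pd

__all__ = [
    "CurveParams",
    "ScanSchedule",
    "GenotypePreset",
    "DEFAULT_SCHEDULE",
    "default_presets",
    "vena_cava_params",
    "CurveGroundTruth",
    "SimulatedCurve",
    "simulate_si_curve",
    "simulate_cohort",
    "simulate_syncytia_fields",
    "simulate_intensity_image",
    "PlantedEffect",
    "simulate_expression_matrix",
]


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    """Deterministic per-generator stream from one global integer seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


@dataclass(frozen=True)
class CurveParams:
    """Parameters of one noiseless biphasic SI curve (times in minutes)."""

    baseline: float = 100.0  # S0, signal units
    uptake_amplitude: float = 0.6  # A1, dimensionless
    uptake_time: float = 8.0  # t1, minutes to the uptake peak
    recovery_amplitude: float = 0.5  # A2, dimensionless
    recovery_onset: float = 30.0  # minutes, logistic centre
    recovery_rate: float = 0.2  # 1/minutes, logistic steepness
    noise_sd: float = 0.0  # signal units, additive Gaussian

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ConfigError("baseline S0 must be positive")
        if self.uptake_amplitude < 0 or self.recovery_amplitude < 0:
            raise ConfigError("amplitudes must be non-negative")
        if self.uptake_time <= 0 or self.recovery_onset <= 0 or self.recovery_rate <= 0:
            raise ConfigError("time constants must be strictly positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")

    def shape(self) -> Callable[[np.ndarray], np.ndarray]:
        """Noiseless SI as a function of time in minutes (vectorized)."""
        s0, a1, t1 = self.baseline, self.uptake_amplitude, self.uptake_time
        a2, onset, rate = self.recovery_amplitude, self.recovery_onset, self.recovery_rate

        def f(t_min: np.ndarray) -> np.ndarray:
            t = np.asarray(t_min, dtype=float)
            uptake = (t / t1) ** 3 * np.exp(3.0 * (1.0 - t / t1))
            recov = 1.0 / (1.0 + np.exp(-rate * (t - onset)))
            return s0 * (1.0 + a1 * uptake + a2 * recov)

        return f


@dataclass(frozen=True)
class ScanSchedule:
    """Fixed dynamic-scan schedule; scan k (1-based) ends at k × scan_duration."""

    n_scans: int = 25
    scan_duration: float = 163.0  # seconds (2 min 43 s)

    def __post_init__(self) -> None:
        if self.n_scans < 3:
            raise ConfigError(f"need >= 3 scans, got {self.n_scans}")
        if self.scan_duration <= 0:
            raise ConfigError("scan_duration must be positive")

    @property
    def times_s(self) -> np.ndarray:
        return self.scan_duration * np.arange(1, self.n_scans + 1)

    @property
    def total_seconds(self) -> float:
        return self.n_scans * self.scan_duration

    @classmethod
    def from_window(cls, window_seconds: float, scan_duration: float = 163.0) -> "ScanSchedule":
        """Schedule filling an acquisition window with whole scans."""
        return cls(n_scans=int(window_seconds // scan_duration), scan_duration=scan_duration)


DEFAULT_SCHEDULE = ScanSchedule()


@dataclass(frozen=True)
class GenotypePreset:
    """Named curve-parameter preset with between-placenta amplitude variation."""

    name: str
    params: CurveParams
    between_placenta_sd: float = 0.10  # fractional CV of both amplitudes

    def __post_init__(self) -> None:
        if self.between_placenta_sd < 0:
            raise ConfigError("between_placenta_sd must be non-negative")


def default_presets(noise_sd: float = 2.0, between_placenta_sd: float = 0.10) -> list[GenotypePreset]:
    """Genotype panel: wild type, three single knockouts of senescence
    regulators, and the Cdkn2a;p53 double knockout, which has the smallest
    recovery amplitude (attenuated agent recycling)."""

    def preset(name: str, a1: float, a2: float) -> GenotypePreset:
        return GenotypePreset(
            name=name,
            params=CurveParams(
                uptake_amplitude=a1, recovery_amplitude=a2, noise_sd=noise_sd
            ),
            between_placenta_sd=between_placenta_sd,
        )

    return [
        preset("WT", 0.60, 0.50),
        preset("Cdkn1a_KO", 0.55, 0.45),
        preset("p53_KO", 0.55, 0.30),
        preset("Cdkn2a_KO", 0.50, 0.25),
        preset("Cdkn2a_p53_DKO", 0.35, 0.10),
    ]


def vena_cava_params(noise_sd: float = 0.0) -> CurveParams:
    """Blood-pool reference curve: fast uptake to an early plateau, no
    biphasic recovery (a macromolecular agent stays intravascular)."""
    return CurveParams(
        baseline=100.0,
        uptake_amplitude=1.5,
        uptake_time=4.0,
        recovery_amplitude=0.0,
        recovery_onset=30.0,
        recovery_rate=0.2,
        noise_sd=noise_sd,
    )


@dataclass(frozen=True)
class CurveGroundTruth:
    """Dense-grid landmark ratios of the noiseless generating curve."""

    initial_enhancement: float
    recovery: float
    first_max_time_s: float
    interior_min_time_s: float
    second_max_time_s: float


def _dense_ground_truth(
    params: CurveParams, schedule: ScanSchedule, oversample: int = 1000
) -> CurveGroundTruth | None:
    """Brute-force landmark ratios on a dense grid over the scan window.

    Returns ``None`` when the noiseless curve has no first maximum or no
    recovery limb (e.g. both amplitudes zero).
    """
    t_s = np.linspace(
        schedule.times_s[0], schedule.times_s[-1], schedule.n_scans * oversample
    )
    y = params.shape()(t_s / 60.0)
    n = y.size
    rising = y[1:-1] >= y[:-2]
    falling = y[1:-1] >= y[2:]
    above = y[1:-1] > y[0]
    candidates = np.flatnonzero(rising & falling & above) + 1
    if candidates.size == 0:
        return None
    first = int(candidates[0])
    interior_min = first + 1 + int(np.argmin(y[first + 1 :]))
    if interior_min == n - 1:
        return None
    second = interior_min + 1 + int(np.argmax(y[interior_min + 1 :]))
    return CurveGroundTruth(
        initial_enhancement=float(y[first] / y[0]),
        recovery=float(y[second] / y[interior_min]),
        first_max_time_s=float(t_s[first]),
        interior_min_time_s=float(t_s[interior_min]),
        second_max_time_s=float(t_s[second]),
    )


@dataclass(frozen=True)
class SimulatedCurve:
    """A generated curve together with its generating parameters and truth."""

    curve: SICurve
    params: CurveParams
    ground_truth: CurveGroundTruth | None


def simulate_si_curve(
    params: CurveParams,
    schedule: ScanSchedule = DEFAULT_SCHEDULE,
    seed: int = 0,
    id: str = "sim",
    group: str = "NA",
) -> SimulatedCurve:
    """Sample one SI curve on the scan schedule (noiseless shape + Gaussian noise).

    Ground-truth landmark ratios are computed from the noiseless shape on a
    dense (1000× oversampled) grid; they are ``None`` when the noiseless
    curve has no biphasic structure.
    """
    times_s = schedule.times_s
    clean = params.shape()(times_s / 60.0)
    rng = _rng(seed, 0)
    noisy = clean + rng.normal(0.0, params.noise_sd, size=clean.shape)
    noisy = np.clip(noisy, 0.0, None)
    curve = SICurve(times=times_s, values=noisy, id=id, group=group)
    return SimulatedCurve(
        curve=curve, params=params, ground_truth=_dense_ground_truth(params, schedule)
    )


def simulate_cohort(
    presets: Sequence[GenotypePreset],
    n_per_group: int,
    schedule: ScanSchedule = DEFAULT_SCHEDULE,
    seed: int = 0,
) -> list[SimulatedCurve]:
    """Generate a multi-genotype cohort with between-placenta amplitude jitter.

    Each placenta's uptake and recovery amplitudes are scaled by
    independent factors ``max(1 + sd·N(0,1), 0.05)``; the jittered noiseless
    parameters define that placenta's ground truth.
    """
    if not presets:
        raise ConfigError("empty preset list")
    if n_per_group < 1:
        raise ConfigError("n_per_group must be >= 1")
    names = [p.name for p in presets]
    if len(set(names)) != len(names):
        raise ConfigError("preset names must be unique")
    out: list[SimulatedCurve] = []
    for gi, preset in enumerate(presets):
        rng = _rng(seed, 1, gi)
        for j in range(n_per_group):
            jitter = np.maximum(
                1.0 + preset.between_placenta_sd * rng.normal(size=2), 0.05
            )
            params = replace(
                preset.params,
                uptake_amplitude=preset.params.uptake_amplitude * jitter[0],
                recovery_amplitude=preset.params.recovery_amplitude * jitter[1],
            )
            curve_seed = int(rng.integers(0, 2**31 - 1))
            out.append(
                simulate_si_curve(
                    params,
                    schedule=schedule,
                    seed=curve_seed,
                    id=f"{preset.name}_{j:02d}",
                    group=preset.name,
                )
            )
    return out


def simulate_syncytia_fields(
    n_fields: int,
    syncytia_per_field: int,
    nuclei_per_syncytium: int | tuple[int, int] = (2, 9),
    p_nucleus_positive: float = 0.3,
    seed: int = 0,
) -> list[SyncytiaField]:
    """Counting fields of syncytia whose nuclei are independently positive.

    ``nuclei_per_syncytium`` is either a fixed count or an inclusive
    uniform integer range; every syncytium carries at least one nucleus.
    """
    if not 0.0 <= p_nucleus_positive <= 1.0:
        raise ConfigError("p_nucleus_positive must lie in [0, 1]")
    if n_fields < 1 or syncytia_per_field < 1:
        raise ConfigError("n_fields and syncytia_per_field must be >= 1")
    rng = _rng(seed, 2)
    if isinstance(nuclei_per_syncytium, int):
        lo = hi = nuclei_per_syncytium
    else:
        lo, hi = nuclei_per_syncytium
    if lo < 1 or hi < lo:
        raise ConfigError("nuclei_per_syncytium must be >= 1 (and lo <= hi)")
    fields = []
    for i in range(n_fields):
        syncytia = []
        for _ in range(syncytia_per_field):
            n_nuclei = int(rng.integers(lo, hi + 1))
            flags = (rng.random(n_nuclei) < p_nucleus_positive).astype(int)
            syncytia.append(tuple(flags))
        fields.append(SyncytiaField(field_id=f"field_{i:03d}", syncytia=tuple(syncytia)))
    return fields


def simulate_intensity_image(
    shape: tuple[int, int] = (128, 128),
    positive_fraction: float = 0.2,
    fg_level: float = 200.0,
    bg_level: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    channel: str = "SA-b-gal",
) -> tuple[IntensityImage, float]:
    """Staining image with a planted positive-area fraction.

    Exactly ``round(positive_fraction × n_pixels)`` randomly placed pixels
    sit at ``fg_level`` before noise; the rest at ``bg_level``. Returns the
    image and the realized (pre-noise) ground-truth fraction.
    """
    if not 0.0 <= positive_fraction <= 1.0:
        raise ConfigError("positive_fraction must lie in [0, 1]")
    if fg_level <= bg_level:
        raise ConfigError("fg_level must exceed bg_level")
    rng = _rng(seed, 3)
    n_pixels = int(np.prod(shape))
    n_fg = round(positive_fraction * n_pixels)
    flat = np.full(n_pixels, float(bg_level))
    fg_idx = rng.permutation(n_pixels)[:n_fg]
    flat[fg_idx] = fg_level
    if noise_sd > 0:
        flat = flat + rng.normal(0.0, noise_sd, size=n_pixels)
    flat = np.clip(flat, 0.0, None)
    image = IntensityImage(pixels=flat.reshape(shape), channel=channel)
    return image, n_fg / n_pixels


@dataclass(frozen=True)
class PlantedEffect:
    """A set of genes sharing one planted linear fold change (> 1)."""

    genes: tuple[str, ...]
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ConfigError("planted fold must exceed 1")


def simulate_expression_matrix(
    n_genes: int = 5000,
    n_per_group: int = 4,
    planted_up: PlantedEffect | None = None,
    planted_down: PlantedEffect | None = None,
    noise_sd_log2: float = 0.1,
    seed: int = 0,
) -> tuple[ExpressionMatrix, dict[str, float]]:
    """Genes × samples matrix with planted between-group fold changes.

    Non-planted genes have equal early/late means in expectation; each
    planted "up" gene's late-group mean is its early mean times the planted
    fold (reciprocal for "down" genes). Sample noise is log-normal with the
    given log2 sd. Returns the matrix and a gene → planted-linear-fold map
    (folds < 1 for down genes).
    """
    if n_genes < 1 or n_per_group < 1:
        raise ConfigError("n_genes and n_per_group must be >= 1")
    if noise_sd_log2 < 0:
        raise ConfigError("noise_sd_log2 must be non-negative")
    genes = [f"g{i:05d}" for i in range(n_genes)]
    gene_set = set(genes)
    truth: dict[str, float] = {}
    for effect, direction in ((planted_up, 1.0), (planted_down, -1.0)):
        if effect is None:
            continue
        unknown = set(effect.genes) - gene_set
        if unknown:
            raise ConfigError(f"planted genes not in matrix: {sorted(unknown)[:5]}")
        for g in effect.genes:
            if g in truth:
                raise ConfigError(f"gene {g!r} planted in both directions")
            truth[g] = effect.fold**direction

    rng = _rng(seed, 4)
    base = 2.0 ** rng.normal(6.0, 1.5, size=n_genes)  # per-gene baseline mean
    fold = np.array([truth.get(g, 1.0) for g in genes])
    samples = [f"early_{i}" for i in range(n_per_group)] + [
        f"late_{i}" for i in range(n_per_group)
    ]
    group = pd.Series(
        ["early"] * n_per_group + ["late"] * n_per_group, index=samples, name="group"
    )
    noise = 2.0 ** rng.normal(0.0, noise_sd_log2, size=(n_genes, 2 * n_per_group))
    means = np.column_stack(
        [np.repeat(base[:, None], n_per_group, axis=1),
         np.repeat((base * fold)[:, None], n_per_group, axis=1)]
    )
    values = pd.DataFrame(means * noise, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionMatrix(values=values, groups=group), truth
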