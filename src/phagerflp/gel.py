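"""Virtual agarose gel: migration model, lane rendering, size inference.

DNA fragments in conventional agarose electrophoresis migrate a distance
approximately linear in the logarithm of their size.  This module fits that
log-linear law, d(s) = a − b·log10(s) with b > 0, to a size ladder by least
squares, renders digest profiles into lanes (Gaussian position noise,
finite detection window, co-migrating bands merged below a resolution
limit), and inverts the law to estimate fragment and genome sizes from band
positions — the procedure by which a genome size is read off a restriction
gel.

The single log-linear regime is adequate over the 0.5–25 kb range resolved
on a 0.8% agarose gel; no reptation correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .digest import DigestProfile

__all__ = [
    "MigrationModel",
    "SizeLadder",
    "Band",
    "GelLane",
    "fit_migration_model",
    "render_lane",
    "infer_sizes",
    "estimate_genome_size",
    "DEFAULT_LADDER",
]

#: Default resolution limit: bands closer than this merge (mm).
RESOLUTION_MM = 0.5
#: Default detection window (min bp, max bp).
DETECTION_WINDOW = (100, 50_000)


@dataclass(frozen=True)
class MigrationModel:
    """Log-linear gel mobility: distance(s) = a − b·log10(s), b > 0."""

    a: float  # intercept, mm
    b: float  # slope, mm per log10(bp)
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("migration slope b must be > 0")

    def distance(self, size_bp: float) -> float:
        if size_bp <= 0:
            raise ValueError("fragment size must be positive")
        return self.a - self.b * np.log10(size_bp)

    def size(self, distance_mm: float) -> float:
        if distance_mm >= self.a:
            raise ValueError(
                f"band distance {distance_mm} mm >= intercept {self.a} mm: "
                "implies size <= 1 bp (non-physical position)"
            )
        return float(10.0 ** ((self.a - distance_mm) / self.b))


@dataclass(frozen=True)
class SizeLadder:
    """Calibration ladder: (known size bp, migration distance mm) pairs."""

    points: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError("ladder needs at least 3 points")
        sizes = [s for s, _ in self.points]
        dists = [d for _, d in self.points]
        if any(s <= 0 for s in sizes):
            raise ValueError("ladder sizes must be positive")
        if not all(a > b for a, b in zip(sizes, sizes[1:])):
            raise ValueError("ladder sizes must be strictly decreasing")
        if not all(a < b for a, b in zip(dists, dists[1:])):
            raise ValueError("ladder distances must be strictly increasing")


def _ideal_ladder(model: MigrationModel, sizes: Sequence[int]) -> SizeLadder:
    return SizeLadder(tuple((s, model.distance(s)) for s in sizes))


#: Default model: positive distances across the whole detection window.
DEFAULT_MODEL = MigrationModel(a=200.0, b=40.0)
#: A lambda/HindIII-like ladder rendered through the default model.
DEFAULT_LADDER = _ideal_ladder(
    DEFAULT_MODEL, (23_130, 9_416, 6_557, 4_361, 2_322, 2_027, 564)
)


@dataclass(frozen=True)
class Band:
    distance_mm: float
    size_bp: int | None  # inferred size; None until infer_sizes
    multiplicity: int = 1


@dataclass(frozen=True)
class GelLane:
    """Detected bands of one lane, sorted by migration distance."""

    lane_id: str
    bands: tuple[Band, ...]
    detection_window: tuple[float, float] = DETECTION_WINDOW

    def __post_init__(self) -> None:
        dists = [b.distance_mm for b in self.bands]
        if dists != sorted(dists):
            raise ValueError("bands must be sorted by ascending distance")
        if any(b.multiplicity < 1 for b in self.bands):
            raise ValueError("band multiplicity must be >= 1")


def fit_migration_model(ladder: SizeLadder) -> MigrationModel:
    """Least-squares fit of migration distance against log10(size).

    Returns the fitted model; its ``rms_residual`` (mm) reports fit quality
    and is 0 for a ladder generated exactly by a log-linear model.
    """
    sizes = np.array([s for s, _ in ladder.points], dtype=float)
    dists = np.array([d for _, d in ladder.points], dtype=float)
    x = np.log10(sizes)
    slope, intercept = np.polyfit(x, dists, 1)
    if slope >= 0:
        raise ValueError("ladder implies non-decreasing mobility with size")
    resid = dists - (intercept + slope * x)
    rms = float(np.sqrt(np.mean(resid**2)))
    return MigrationModel(a=float(intercept), b=float(-slope), rms_residual=rms)


def render_lane(
    profile: DigestProfile,
    model: MigrationModel,
    noise_sd: float = 0.0,
    detection: tuple[float, float] = DETECTION_WINDOW,
    seed: int | None = None,
    resolution_mm: float = RESOLUTION_MM,
) -> GelLane:
    """Render a digest profile as a gel lane.

    Each fragment inside the detection window becomes a band at
    d(size) + N(0, noise_sd²); fragments outside the window are dropped
    (they run off the gel or are too faint).  Bands closer than
    ``resolution_mm`` merge into one band carrying the summed multiplicity,
    positioned at the mean of the merged distances.  Deterministic for a
    given seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lo, hi = detection
    rng = np.random.default_rng(seed)
    kept = [s for s in profile.fragments if lo <= s <= hi]
    dists = sorted(
        model.distance(s) + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
        for s in kept
    )

    # full precision is kept in memory; table writers round to 0.01 mm
    bands: list[Band] = []
    cluster: list[float] = []
    for d in dists:
        if cluster and d - cluster[-1] >= resolution_mm:
            bands.append(Band(float(np.mean(cluster)), None, len(cluster)))
            cluster = []
        cluster.append(d)
    if cluster:
        bands.append(Band(float(np.mean(cluster)), None, len(cluster)))

    return GelLane(
        lane_id=profile.genome_id, bands=tuple(bands), detection_window=detection
    )


def infer_sizes(lane: GelLane, model: MigrationModel) -> list[int]:
    """Invert the migration model: size = 10^((a − d)/b) per band, integer bp."""
    return [int(round(model.size(b.distance_mm))) for b in lane.bands]


def estimate_genome_size(lane: GelLane, model: MigrationModel) -> int:
    """Estimate genome size as the multiplicity-weighted sum of band sizes.

    Fragments below the detection window never appear in the lane, so the
    estimate is biased low whenever small fragments were dropped.
    """
    if not lane.bands:
        raise ValueError(f"lane {lane.lane_id!r} has no bands")
    sizes = infer_sizes(lane, model)
    return int(sum(s * b.multiplicity for s, b in zip(sizes, lane.bands)))
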