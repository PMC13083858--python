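"""Quantification procedures for gravitropism and transport experiments.

Three small, exactly specified computations:

* circular sector binning of root bending angles (18 sectors of 20°, or 12
  of 30°), reported as per-sector counts and percentages of seedlings;
* relative radiotracer import into protoplasts, as percent change of
  protoplast-associated counts between t = 0 and t = 15 min;
* relative western-band quantity: background-adjusted band volume divided
  by the background-adjusted reference band volume (reference = 1.00).

Plus a generator of synthetic bending-angle samples (wrapped normal).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DomainError


@dataclass
class AngleHistogram:
    width: float                 # sector width, degrees
    sector_edges: np.ndarray     # (n_sectors + 1,) degrees, half-open [lo, hi)
    counts: np.ndarray           # (n_sectors,)
    percentages: np.ndarray      # (n_sectors,), sums to 100
    n: int

    @property
    def n_sectors(self) -> int:
        return len(self.counts)


def bin_root_angles(angles, width: float = 20.0) -> AngleHistogram:
    """Group root-growth angles into sectors of ``width`` degrees.

    Angles are reduced modulo 360 into [0, 360) and counted in half-open
    sectors [k·width, (k+1)·width); bar lengths are percentages of the
    sample.  ``width`` must divide 360 exactly (e.g. 20° → 18 sectors,
    30° → 12 sectors).
    """
    if not width > 0:
        raise ConfigError(f"sector width must be > 0, got {width!r}")
    n_sectors = 360.0 / width
    if abs(n_sectors - round(n_sectors)) > 1e-9:
        raise ConfigError(f"sector width {width} does not divide 360")
    n_sectors = int(round(n_sectors))
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise DomainError("empty angle list")
    if not np.all(np.isfinite(a)):
        raise DomainError("angles must be finite")
    a = np.mod(a, 360.0)
    a[a >= 360.0] = 0.0  # np.mod(-eps, 360) can round to exactly 360
    edges = np.arange(n_sectors + 1) * width
    idx = np.floor(a / width).astype(int)
    idx[idx >= n_sectors] = n_sectors - 1  # guard a == 360-eps rounding up
    counts = np.bincount(idx, minlength=n_sectors)
    return AngleHistogram(width=float(width), sector_edges=edges,
                          counts=counts,
                          percentages=100.0 * counts / a.size, n=int(a.size))


def relative_import(x15: float, x0: float) -> float:
    """Relative radiotracer import into protoplasts, percent.

    ``x0`` and ``x15`` are protoplast-associated radioactivity counts at
    t = 0 and t = 15 min; returns (x15 − x0) / x0 × 100.
    """
    if not x0 > 0:
        raise DomainError(f"baseline counts must be > 0, got {x0!r}")
    return (x15 - x0) / x0 * 100.0


def relative_band_quantity(volumes, backgrounds, reference_index: int):
    """Relative western-band quantities against a designated reference band.

    ratio_i = (volume_i − background_i) / (volume_ref − background_ref);
    the reference band has ratio 1.00 by construction.
    """
    v = np.asarray(volumes, dtype=float)
    b = np.asarray(backgrounds, dtype=float)
    if v.shape != b.shape or v.ndim != 1:
        raise DomainError("volumes and backgrounds must be 1-D and equal length")
    if not 0 <= reference_index < v.size:
        raise DomainError(f"reference index {reference_index} out of range")
    adj = v - b
    ref = adj[reference_index]
    if not ref > 0:
        raise DomainError("background-adjusted reference volume must be > 0")
    return adj / ref


def sample_bending_angles(n: int, mean_deg: float = 0.0, sd_deg: float = 25.0,
                          seed: int | None = None) -> np.ndarray:
    """Synthetic root bending angles (wrapped normal), degrees in [0, 360).

    Emulates the distribution of root-tip orientations after a
    gravistimulation time course: most roots re-orient near the gravity
    vector (mean 0° deviation) with seedling-to-seedling spread ``sd_deg``.
    """
    if n < 1:
        raise DomainError("n must be >= 1")
    if sd_deg < 0:
        raise DomainError("sd_deg must be >= 0")
    rng = np.random.default_rng(seed)
    return np.mod(rng.normal(mean_deg, sd_deg, size=n), 360.0)
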