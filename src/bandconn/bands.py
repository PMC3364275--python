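"""Frequency band definitions for BOLD sub-band decomposition.

Resting-state BOLD analyses conventionally restrict attention to the
low-frequency interval 0.025-0.100 Hz, where spontaneous neuronal
fluctuations dominate over scanner drift (below) and physiological noise
(above).  The multi-spectrum characterization splits this interval into
five contiguous sub-bands so that connectivity can be estimated per band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BandSpec", "default_bands", "equal_split_bands", "validate_partition"]


@dataclass(frozen=True)
class BandSpec:
    """A named frequency interval in Hz.

    Within a partition the interval is half-open, ``[f_lo, f_hi)``; the last
    band of a partition is closed at its upper edge so that the bands
    partition the discrete spectrum of the union interval exactly.
    """

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_lo < self.f_hi):
            raise ValueError(
                f"band {self.name!r}: need 0 <= f_lo < f_hi, got [{self.f_lo}, {self.f_hi}]"
            )

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo


#: Conventional five-band split of the 0.025-0.100 Hz low-frequency interval.
_DEFAULT_EDGES = [
    ("Band1", 0.025, 0.039),
    ("Band2", 0.039, 0.054),
    ("Band3", 0.054, 0.068),
    ("Band4", 0.068, 0.082),
    ("Band5", 0.082, 0.100),
]


def default_bands() -> list[BandSpec]:
    """The five standard sub-bands of the 0.025-0.100 Hz interval.

    The printed edges (0.039, 0.054, 0.068, 0.082 Hz) are kept verbatim even
    though they are rounded rather than an exact equal division; use
    :func:`equal_split_bands` for exact fifths.
    """
    return [BandSpec(name, lo, hi) for name, lo, hi in _DEFAULT_EDGES]


def equal_split_bands(f_lo: float = 0.025, f_hi: float = 0.100, n: int = 5) -> list[BandSpec]:
    """Split ``[f_lo, f_hi]`` into ``n`` exactly equal contiguous bands."""
    edges = np.linspace(f_lo, f_hi, n + 1)
    return [BandSpec(f"Band{k + 1}", edges[k], edges[k + 1]) for k in range(n)]


def validate_partition(bands: list[BandSpec]) -> None:
    """Check that bands are ordered, non-overlapping and contiguous-or-gapped.

    Raises ``ValueError`` on an empty list, unordered bands, or overlap.
    """
    if not bands:
        raise ValueError("band partition is empty")
    for prev, cur in zip(bands, bands[1:]):
        if cur.f_lo < prev.f_hi:
            raise ValueError(
                f"bands {prev.name!r} and {cur.name!r} overlap or are unordered "
                f"({prev.f_hi} > {cur.f_lo})"
            )
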