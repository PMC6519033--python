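"""Piecewise-constant recombination maps.

A map assigns a per-bp population recombination rate ``rho = 4*Ne*r`` to every
position of a sequence of length ``length_bp``.  Blocks tile ``[0, L)`` exactly
(0-based, half-open coordinates); there is one more rate than interior
breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RecombinationMap", "make_hotspot_map"]


@dataclass(frozen=True)
class RecombinationMap:
    """Piecewise-constant per-bp rho over ``[0, length_bp)``.

    Parameters
    ----------
    length_bp
        Total sequence length L.
    breakpoints
        Strictly increasing interior breakpoints in ``(0, L)``.
    rates
        Per-bp rho for each block; ``len(rates) == len(breakpoints) + 1``.
    """

    length_bp: int
    breakpoints: np.ndarray
    rates: np.ndarray

    def __init__(self, length_bp, breakpoints, rates):
        object.__setattr__(self, "length_bp", int(length_bp))
        object.__setattr__(
            self, "breakpoints", np.asarray(breakpoints, dtype=float)
        )
        object.__setattr__(self, "rates", np.asarray(rates, dtype=float))
        self._validate()

    def _validate(self) -> None:
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")
        b = self.breakpoints
        if b.ndim != 1 or self.rates.ndim != 1:
            raise ValueError("breakpoints and rates must be 1-D")
        if len(self.rates) != len(b) + 1:
            raise ValueError(
                f"need one more rate ({len(self.rates)}) than interior "
                f"breakpoints ({len(b)})"
            )
        if len(b) and (np.any(np.diff(b) <= 0) or b[0] <= 0 or b[-1] >= self.length_bp):
            raise ValueError("breakpoints must be strictly increasing within (0, L)")
        if np.any(self.rates < 0):
            raise ValueError("rates must be non-negative")
        if np.any(~np.isfinite(self.rates)):
            raise ValueError("rates must be finite")

    @property
    def n_blocks(self) -> int:
        return len(self.rates)

    @property
    def edges(self) -> np.ndarray:
        """Block edges including 0 and L (length ``n_blocks + 1``)."""
        return np.concatenate([[0.0], self.breakpoints, [float(self.length_bp)]])

    def blocks(self) -> list[tuple[float, float, float]]:
        """Blocks as ``(start, end, rate)`` triples."""
        e = self.edges
        return [(e[i], e[i + 1], r) for i, r in enumerate(self.rates)]

    def rate_at(self, positions) -> np.ndarray:
        """Per-bp rho at each position (vectorized)."""
        pos = np.asarray(positions, dtype=float)
        if np.any(pos < 0) or np.any(pos >= self.length_bp):
            raise ValueError("positions must lie in [0, L)")
        idx = np.searchsorted(self.breakpoints, pos, side="right")
        return self.rates[idx]

    @classmethod
    def constant(cls, length_bp: int, rho: float) -> "RecombinationMap":
        return cls(length_bp, np.empty(0), np.array([float(rho)]))

    def __eq__(self, other) -> bool:
        if not isinstance(other, RecombinationMap):
            return NotImplemented
        return (
            self.length_bp == other.length_bp
            and np.array_equal(self.breakpoints, other.breakpoints)
            and np.array_equal(self.rates, other.rates)
        )


def make_hotspot_map(
    length_bp: int,
    background_rho: float,
    hotspots: list[tuple[float, float, float]],
) -> RecombinationMap:
    """Build a hotspot map on a constant background.

    Each hotspot is ``(start, length, intensity)``: the block
    ``[start, start+length)`` gets rate ``background_rho * intensity``.
    Hotspots must be non-overlapping, lie inside ``[0, L)`` and have
    intensity > 1.
    """
    if background_rho < 0:
        raise ValueError("background_rho must be non-negative")
    hs = sorted((float(s), float(l), float(f)) for s, l, f in hotspots)
    breakpoints: list[float] = []
    rates: list[float] = []
    cursor = 0.0
    for start, length, intensity in hs:
        if length <= 0:
            raise ValueError("hotspot length must be positive")
        if intensity <= 1:
            raise ValueError("hotspot intensity must exceed 1")
        end = start + length
        if start < cursor:
            raise ValueError("hotspots overlap or are out of order")
        if start < 0 or end > length_bp:
            raise ValueError("hotspot outside the sequence")
        if start > cursor:
            rates.append(background_rho)
            breakpoints.append(start)
        rates.append(background_rho * intensity)
        if end < length_bp:
            breakpoints.append(end)
        cursor = end
    if cursor < length_bp or not rates:
        rates.append(background_rho)
    return RecombinationMap(length_bp, np.array(breakpoints), np.array(rates))
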