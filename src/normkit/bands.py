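"""Frequency band schemes for relative band power."""

from __future__ import annotations

from dataclasses import dataclass, field


#: Default five-band scheme (Hz, half-open intervals [low, high)).
DEFAULT_BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 47.5),
}


@dataclass(frozen=True)
class BandScheme:
    """Ordered, contiguous, non-overlapping frequency bands.

    Each band is a half-open interval ``[low, high)`` in Hz.  The analysis
    range is the union of the bands; relative band power is computed with
    respect to the total power inside that range.
    """

    bands: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_EDGES)
    )

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("band scheme must contain at least one band")
        edges = list(self.bands.values())
        for name, (low, high) in self.bands.items():
            if not (0 <= low < high):
                raise ValueError(f"band {name!r} has invalid edges [{low}, {high})")
        for (_, prev_high), (low, _) in zip(edges, edges[1:]):
            if low != prev_high:
                raise ValueError("bands must be contiguous and non-overlapping")

    @property
    def names(self) -> list[str]:
        return list(self.bands)

    @property
    def analysis_range(self) -> tuple[float, float]:
        edges = list(self.bands.values())
        return edges[0][0], edges[-1][1]

    @property
    def highest_edge(self) -> float:
        return self.analysis_range[1]

    def bandwidth(self, name: str) -> float:
        low, high = self.bands[name]
        return high - low

    def to_dict(self) -> list[list]:
        """Order-preserving serialization: a list of [name, low, high]."""
        return [[name, low, high] for name, (low, high) in self.bands.items()]

    @classmethod
    def from_dict(cls, d) -> "BandScheme":
        if isinstance(d, dict):
            return cls({name: (float(lo), float(hi)) for name, (lo, hi) in d.items()})
        return cls({name: (float(lo), float(hi)) for name, lo, hi in d})


DEFAULT_BANDS = BandScheme()
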