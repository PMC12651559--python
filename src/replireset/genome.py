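"""Circular bacterial chromosome coordinate system.

A :class:`GenomeMap` fixes the frame of reference used by the coverage and
synthetic modules: total length, the replication origin (*oriC*), the
terminus window used for copy-number normalisation, optional masked
intervals, and named loci (for example a site of engineered head-on
transcription-replication conflict).

All coordinates are 0-based, intervals are half-open ``[start, end)``, and
arithmetic wraps around the circle.  The two *replichores* are the halves of
the chromosome replicated by the clockwise fork (from oriC towards the
terminus in increasing-coordinate direction; called "right" here) and the
counter-clockwise fork ("left").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

__all__ = ["GenomeMap", "ecoli_k12"]


@dataclass
class GenomeMap:
    """Circular genome reference frame.

    Parameters
    ----------
    length : int
        Chromosome length in bp.
    oric : int
        Coordinate of the replication origin.
    terminus_window : tuple of int
        Half-open interval used as the terminus reference for copy-number
        normalisation.  Should sit diametrically opposite oriC.
    masked_intervals : list of tuple
        Half-open intervals to exclude from analysis (e.g. the terminus
        region in DNA-end mapping experiments).
    loci : dict
        Named coordinates, e.g. ``{"invD": 3428000}``.
    """

    length: int
    oric: int
    terminus_window: tuple[int, int]
    masked_intervals: list[tuple[int, int]] = field(default_factory=list)
    loci: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("genome length must be positive")
        if not (0 <= self.oric < self.length):
            raise ValueError("oriC outside genome")
        for name, pos in self.loci.items():
            if not (0 <= pos < self.length):
                raise ValueError(f"locus {name!r} outside genome")

    # -- circular arithmetic -------------------------------------------------

    def wrap(self, pos: int) -> int:
        """Map any integer coordinate onto [0, length)."""
        return int(pos) % self.length

    @property
    def terminus(self) -> int:
        """Midpoint of the terminus window (wrap-aware)."""
        start, end = self.terminus_window
        span = (end - start) % self.length
        return self.wrap(start + span // 2)

    def circular_distance(self, a: int, b: int) -> int:
        """Shortest distance between two coordinates on the circle."""
        d = abs(self.wrap(a) - self.wrap(b))
        return min(d, self.length - d)

    def clockwise_distance(self, a: int, b: int) -> int:
        """Distance from a to b moving in increasing-coordinate direction."""
        return (self.wrap(b) - self.wrap(a)) % self.length

    # -- replichore geometry -------------------------------------------------

    def replichore(self, pos: int) -> str:
        """Which replichore a coordinate lies on.

        "right" = replicated by the fork travelling clockwise (increasing
        coordinates) from oriC to the terminus; "left" = the other half.
        """
        d_cw = self.clockwise_distance(self.oric, pos)
        span_right = self.clockwise_distance(self.oric, self.terminus)
        return "right" if d_cw <= span_right else "left"

    def origin_distance(self, pos: int) -> int:
        """Distance from oriC along the replichore containing ``pos``."""
        if self.replichore(pos) == "right":
            return self.clockwise_distance(self.oric, pos)
        return self.clockwise_distance(pos, self.oric)

    def arm_length(self, replichore: str) -> int:
        span_right = self.clockwise_distance(self.oric, self.terminus)
        return span_right if replichore == "right" else self.length - span_right

    def mirror_locus(self, pos: int) -> int:
        """The point on the other replichore equidistant from oriC."""
        d = self.origin_distance(pos)
        if self.replichore(pos) == "right":
            return self.wrap(self.oric - d)
        return self.wrap(self.oric + d)

    def position_at(self, replichore: str, origin_distance: int) -> int:
        """Coordinate at a given distance from oriC on a named replichore."""
        if replichore == "right":
            return self.wrap(self.oric + origin_distance)
        return self.wrap(self.oric - origin_distance)

    def is_masked(self, pos: int) -> bool:
        p = self.wrap(pos)
        for start, end in self.masked_intervals:
            if start <= end:
                if start <= p < end:
                    return True
            elif p >= start or p < end:  # interval wraps origin of coordinates
                return True
        return False

    # -- serialisation -------------------------------------------------------

    def to_yaml(self, path) -> None:
        data = {
            "length": int(self.length),
            "oric": int(self.oric),
            "terminus_window": [int(v) for v in self.terminus_window],
            "masked_intervals": [[int(a), int(b)] for a, b in self.masked_intervals],
            "loci": {k: int(v) for k, v in self.loci.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "GenomeMap":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            length=int(data["length"]),
            oric=int(data["oric"]),
            terminus_window=tuple(data["terminus_window"]),
            masked_intervals=[tuple(iv) for iv in data.get("masked_intervals", [])],
            loci={k: int(v) for k, v in data.get("loci", {}).items()},
        )


def ecoli_k12() -> GenomeMap:
    """Reference frame for the E. coli K-12 MG1655 chromosome (NC_000913.3).

    oriC and the dif/ter region coordinates follow the standard annotation;
    the ``invD`` locus marks an inverted rrnD ribosomal RNA operon that
    creates a localised head-on transcription-replication conflict.  All
    values are defaults only and are overridable via YAML configs.
    """
    return GenomeMap(
        length=4_641_652,
        oric=3_925_744,
        terminus_window=(1_580_000, 1_620_000),
        masked_intervals=[],
        loci={"invD": 3_423_000},
    )
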