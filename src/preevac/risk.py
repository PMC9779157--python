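"""Standardized risk-context factors.

Three external drivers enter the escape-decision model, each mapped onto the
unit interval through a four-level ordinal scale:

* **RCS** — intensity of the hazard event itself,
* **DFD** — metric distance between the pedestrian and the hazard source,
* **RNC** — reaction of the neighbourhood crowd (herding pressure).

Level ``L1`` is the most alarming state (scale 1.00) and ``L4`` the least
(scale 0.25).  Distances are binned with half-open intervals ``[lo, hi)`` so
every distance maps to exactly one level; the crowd-reaction level is derived
from the fraction of nearby agents that have already reacted, with quartile
cut points.  A continuous (unquantized) mode is available but off by default.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "RiskLevel",
    "RiskContext",
    "standardize_level",
    "dfd_level",
    "rnc_level",
    "context_at",
    "level_table",
]

#: Ordinal level -> unit-interval scale (bijective).
_LEVEL_SCALE = {1: 1.00, 2: 0.75, 3: 0.50, 4: 0.25}

#: Distance bin edges in metres; bin k (0-based) is [edge_k, edge_{k+1}).
_DFD_EDGES = (20.0, 40.0, 60.0)

#: Length scale of the continuous (unquantized) distance mapping.
_DFD_CONTINUOUS_SPAN = 80.0


class RiskLevel(enum.IntEnum):
    """Four-level ordinal risk scale; ``L1`` strongest, ``L4`` weakest."""

    L1 = 1
    L2 = 2
    L3 = 3
    L4 = 4

    @property
    def scale(self) -> float:
        """Unit-interval value of this level."""
        return _LEVEL_SCALE[int(self)]


def standardize_level(level: int | RiskLevel, invert: bool = False) -> float:
    """Map an ordinal risk level to its unit-interval scale value.

    Parameters
    ----------
    level
        Ordinal level in ``{1, 2, 3, 4}`` (or a :class:`RiskLevel`).
    invert
        If true, reverse the ordering so that level 4 maps to 1.00.  Useful
        when an event description numbers intensities in the opposite
        direction from the standard table.
    """
    lvl = int(level)
    if lvl not in _LEVEL_SCALE:
        raise ValueError(f"risk level must be in 1..4, got {level!r}")
    return _LEVEL_SCALE[5 - lvl] if invert else _LEVEL_SCALE[lvl]


def dfd_level(distance: float) -> RiskLevel:
    """Ordinal distance-from-danger level for a metric distance.

    Bins are half-open: ``[0, 20) -> L1``, ``[20, 40) -> L2``,
    ``[40, 60) -> L3``, ``[60, inf) -> L4``.
    """
    d = float(distance)
    if not math.isfinite(d) or d < 0:
        raise ValueError(f"distance must be finite and >= 0, got {distance!r}")
    for k, edge in enumerate(_DFD_EDGES):
        if d < edge:
            return RiskLevel(k + 1)
    return RiskLevel.L4


def rnc_level(fraction: float) -> RiskLevel:
    """Crowd-reaction level from the fraction of already-reacting neighbours.

    Quartile cut points: ``f >= 0.75 -> L1``, ``[0.50, 0.75) -> L2``,
    ``[0.25, 0.50) -> L3``, ``f < 0.25 -> L4``.
    """
    f = float(fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"reacting fraction must lie in [0, 1], got {fraction!r}")
    if f >= 0.75:
        return RiskLevel.L1
    if f >= 0.50:
        return RiskLevel.L2
    if f >= 0.25:
        return RiskLevel.L3
    return RiskLevel.L4


@dataclass(frozen=True)
class RiskContext:
    """Per-period standardized context triple (RCS, DFD, RNC).

    All three values lie in ``[0, 1]``; in the default quantized mode they
    take one of the four scale values ``{1.00, 0.75, 0.50, 0.25}``.
    """

    rcs: float
    dfd: float
    rnc: float
    period: int = 0

    def __post_init__(self) -> None:
        for name in ("rcs", "dfd", "rnc"):
            v = getattr(self, name)
            if not 0.0 <= float(v) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if self.period < 0:
            raise ValueError(f"period must be >= 0, got {self.period!r}")

    @property
    def is_quantized(self) -> bool:
        """Whether all three values sit on the four-level scale."""
        scales = set(_LEVEL_SCALE.values())
        return all(getattr(self, n) in scales for n in ("rcs", "dfd", "rnc"))

    def as_dict(self) -> Mapping[str, float]:
        return {"rcs": self.rcs, "dfd": self.dfd, "rnc": self.rnc}


def _continuous_dfd(distance: float) -> float:
    return min(1.0, max(0.0, 1.0 - distance / _DFD_CONTINUOUS_SPAN))


def context_at(
    pedestrian,
    scene,
    t: int,
    *,
    reacting_fraction: float = 0.0,
    continuous: bool = False,
    invert_fire_scale: bool = False,
) -> RiskContext:
    """Standardized risk context of one pedestrian at decision period ``t``.

    ``rcs`` is the standardized fire level of the scene's event; ``dfd``
    derives from the Euclidean distance to the fire source; ``rnc`` from the
    supplied fraction of reacting neighbours (the simulator computes that
    fraction from its state within its neighbourhood radius).

    Pure: identical arguments always yield the identical triple.
    """
    if pedestrian.position is None:
        raise ValueError("pedestrian has no position; context requires a placed agent")
    x, y = pedestrian.position
    x0, y0, x1, y1 = scene.bounds
    if not (x0 <= x <= x1 and y0 <= y <= y1):
        raise ValueError(f"pedestrian position {(x, y)} lies outside scene bounds {scene.bounds}")
    fx, fy = scene.fire.point
    distance = math.hypot(x - fx, y - fy)

    rcs = standardize_level(scene.fire.level, invert=invert_fire_scale)
    if continuous:
        dfd = _continuous_dfd(distance)
        rnc = float(reacting_fraction)
        if not 0.0 <= rnc <= 1.0:
            raise ValueError(f"reacting fraction must lie in [0, 1], got {reacting_fraction!r}")
    else:
        dfd = dfd_level(distance).scale
        rnc = rnc_level(reacting_fraction).scale
    return RiskContext(rcs=rcs, dfd=dfd, rnc=rnc, period=int(t))


def level_table() -> dict:
    """The level/scale mapping and bin edges, e.g. for dumping to JSON docs."""
    return {
        "levels": {f"L{k}": v for k, v in _LEVEL_SCALE.items()},
        "dfd_bin_edges_m": list(_DFD_EDGES),
        "rnc_cut_points": [0.25, 0.50, 0.75],
        "continuous_dfd_span_m": _DFD_CONTINUOUS_SPAN,
    }
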