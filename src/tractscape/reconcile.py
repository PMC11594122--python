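"""Census-tract geography reconciliation.

US census tracts are identified two ways in practice: a decimal "name"
of the form ``XXXX.YY`` and an all-digit GEOID whose last two digits
carry the same subdivision suffix. Health-outcome tables and boundary
shapefiles frequently subdivide tracts differently, so before imagery
can be joined to outcomes both layers must be collapsed to a common
base: subdivision digits are zeroed, polygons sharing a base id are
dissolved into one, and outcome rates of the merged members are combined
as a population-weighted mean

    merged_rate = sum_i(pop_i * rate_i) / sum_i(pop_i).

The module also carries Douglas-Peucker boundary simplification used to
produce compact footprint polygons for product queries.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import shapely
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "TractRecord",
    "JoinedTract",
    "MatchReport",
    "normalize_id",
    "tract_code",
    "merge_outcomes",
    "dissolve_by_base",
    "match_joined_sets",
    "simplify_boundary",
    "simplify_to_max_vertices",
]

_NAME_RE = re.compile(r"^\d{1,5}\.\d{2}$")
_GEOID_RE = re.compile(r"^\d{3,}$")


@dataclass
class TractRecord:
    """One census tract: identifier, geometry, population, outcome rate.

    ``outcome_rate`` is a crude prevalence in percent (e.g. share of
    adults with BMI >= 30) and may be missing. ``population`` is the
    weight used when subdivided tracts are merged.
    """

    geoid: str
    geometry: Optional[BaseGeometry] = None
    population: int = 0
    outcome_rate: Optional[float] = None
    name: Optional[str] = None

    def __post_init__(self):
        if not self.geoid or not self.geoid.replace(".", "").isdigit():
            raise ValueError(f"geoid must be a non-empty digit string, got {self.geoid!r}")
        if self.population < 0:
            raise ValueError("population must be non-negative")
        if self.outcome_rate is not None and not (0.0 <= self.outcome_rate <= 100.0):
            raise ValueError(f"outcome_rate must lie in [0, 100], got {self.outcome_rate}")


@dataclass
class JoinedTract:
    """A dissolved tract: union geometry, summed population, weighted rate."""

    base_id: str
    geometry: Optional[BaseGeometry]
    population: int
    outcome_rate: Optional[float]
    n_members: int


@dataclass
class MatchReport:
    matched: list[str] = field(default_factory=list)
    unmatched_a: list[str] = field(default_factory=list)
    unmatched_b: list[str] = field(default_factory=list)


def normalize_id(identifier: str) -> str:
    """Zero the two trailing subdivision digits of a tract identifier.

    Handles both dialects: decimal names ("1201.05" -> "1201.00") and
    all-digit GEOIDs ("29510124612" -> "29510124600"). Idempotent.
    """
    identifier = str(identifier).strip()
    if _NAME_RE.match(identifier):
        stem = identifier.rsplit(".", 1)[0]
        return f"{stem}.00"
    if _GEOID_RE.match(identifier):
        return identifier[:-2] + "00"
    raise ValueError(
        f"identifier {identifier!r} matches neither the decimal tract-name dialect "
        "('XXXX.YY') nor the all-digit GEOID dialect"
    )


def tract_code(identifier: str) -> str:
    """Six-digit tract code shared by both identifier dialects.

    A decimal name "0123.00" and a full GEOID ending in "012300" refer
    to the same tract; the common key is the 6-digit code (4-digit base
    + 2 subdivision digits). Useful for matching a name-keyed layer
    against a GEOID-keyed one.
    """
    norm = normalize_id(identifier)
    if "." in norm:
        stem, sub = norm.split(".")
        return f"{int(stem):04d}{sub}"
    return norm[-6:]


def merge_outcomes(members: Sequence[tuple[float, Optional[float]]]) -> float:
    """Population-weighted mean outcome rate of merged subdivisions.

    ``members`` is a sequence of (population, rate) pairs. The merged
    rate is sum(w*x)/sum(w); it always lies within the range of the
    member rates.

    Raises
    ------
    ValueError
        If any member rate is missing (offenders listed) or if the total
        population weight is zero.
    """
    if not members:
        raise ValueError("merge_outcomes requires at least one member")
    missing = [i for i, (_, rate) in enumerate(members) if rate is None]
    if missing:
        raise ValueError(f"members at positions {missing} have missing outcome rates")
    total_w = float(sum(w for w, _ in members))
    if total_w <= 0:
        raise ValueError("total population weight is zero; weighted merge undefined")
    return float(sum(w * x for w, x in members)) / total_w


def dissolve_by_base(records: Iterable[TractRecord]) -> list[JoinedTract]:
    """Dissolve tracts sharing a base id into single joined polygons.

    Geometries are unioned, populations summed, and outcome rates merged
    with :func:`merge_outcomes`. Groups in which no member carries a
    rate dissolve with ``outcome_rate=None`` (a bare boundary layer has
    no outcome attribute to merge); groups with a partial rate coverage
    raise, since silently dropping members would bias the weighted mean.
    """
    groups: dict[str, list[TractRecord]] = {}
    for rec in records:
        key = normalize_id(rec.name if rec.name is not None else rec.geoid)
        groups.setdefault(key, []).append(rec)

    joined = []
    for base_id in sorted(groups):
        members = groups[base_id]
        geoms = [m.geometry for m in members if m.geometry is not None]
        geometry = shapely.union_all(geoms) if geoms else None
        population = int(sum(m.population for m in members))
        if all(m.outcome_rate is None for m in members):
            rate = None
        else:
            rate = merge_outcomes([(m.population, m.outcome_rate) for m in members])
        joined.append(
            JoinedTract(
                base_id=base_id,
                geometry=geometry,
                population=population,
                outcome_rate=rate,
                n_members=len(members),
            )
        )
    return joined


def match_joined_sets(ids_a: Iterable[str], ids_b: Iterable[str]) -> MatchReport:
    """Intersect two normalized id sets and report the unmatched remainder."""
    set_a, set_b = set(ids_a), set(ids_b)
    report = MatchReport(
        matched=sorted(set_a & set_b),
        unmatched_a=sorted(set_a - set_b),
        unmatched_b=sorted(set_b - set_a),
    )
    logger.info(
        "matched %d ids; %d unmatched in layer A, %d unmatched in layer B",
        len(report.matched),
        len(report.unmatched_a),
        len(report.unmatched_b),
    )
    return report


def _vertex_count(polygon) -> int:
    return len(polygon.exterior.coords)


def simplify_boundary(polygon, tolerance: float):
    """Douglas-Peucker simplification of a polygon boundary.

    Vertex count is non-increasing in ``tolerance``; tolerance 0 returns
    the input unchanged. The result remains a closed ring.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    if polygon.is_empty or polygon.geom_type not in ("Polygon", "MultiPolygon"):
        raise ValueError(f"expected a polygon, got {polygon.geom_type}")
    if polygon.geom_type == "Polygon" and _vertex_count(polygon) < 4:
        raise ValueError("degenerate ring with fewer than 4 coordinates")
    if tolerance == 0:
        return polygon
    return shapely.simplify(polygon, tolerance, preserve_topology=False)


def simplify_to_max_vertices(polygon, max_vertices: int, max_iter: int = 60):
    """Search (by bisection on tolerance) the gentlest simplification
    with at most ``max_vertices`` exterior vertices.

    Returns ``(simplified_polygon, tolerance)``. Douglas-Peucker is
    tolerance-parameterized, so a target vertex count (a compact 54-gon
    footprint for a query string, say) must be reached by searching the
    tolerance.
    """
    if max_vertices < 4:
        raise ValueError("a closed ring needs at least 4 coordinates")
    if _vertex_count(polygon) <= max_vertices:
        return polygon, 0.0
    minx, miny, maxx, maxy = polygon.bounds
    lo, hi = 0.0, max(maxx - minx, maxy - miny)
    while _vertex_count(simplify_boundary(polygon, hi)) > max_vertices:
        hi *= 2.0
    best, best_tol = simplify_boundary(polygon, hi), hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        cand = simplify_boundary(polygon, mid)
        if _vertex_count(cand) <= max_vertices:
            best, best_tol = cand, mid
            hi = mid
        else:
            lo = mid
    return best, best_tol
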