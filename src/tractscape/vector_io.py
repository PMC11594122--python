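"""Vector-layer and tabular I/O: GeoJSON tract layers, outcome CSVs, manifests.

GeoJSON is written with a ``crs`` member naming the planar coordinate
system of the synthetic data (documented as planar meters, not
geodetic coordinates). Attributes can also round-trip through a plain
CSV keyed by geoid, matching the way outcome tables are published
separately from boundary files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml
from shapely.geometry import mapping, shape

from .reconcile import JoinedTract, TractRecord

__all__ = [
    "write_tracts_geojson",
    "read_tracts_geojson",
    "write_boundary_geojson",
    "read_boundary_geojson",
    "write_outcomes_csv",
    "read_outcomes_csv",
    "join_attributes",
    "write_manifest",
    "read_manifest",
]


def _feature(geometry, properties) -> dict:
    return {
        "type": "Feature",
        "geometry": mapping(geometry) if geometry is not None else None,
        "properties": properties,
    }


def _collection(features: list[dict], crs: str) -> dict:
    return {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs}},
        "features": features,
    }


def write_tracts_geojson(path, tracts: Sequence, crs: str) -> None:
    """Write TractRecords or JoinedTracts as a GeoJSON FeatureCollection."""
    features = []
    for t in tracts:
        if isinstance(t, JoinedTract):
            props = {
                "base_id": t.base_id,
                "population": t.population,
                "outcome_rate": t.outcome_rate,
                "n_members": t.n_members,
            }
        else:
            props = {
                "geoid": t.geoid,
                "name": t.name,
                "population": t.population,
                "outcome_rate": t.outcome_rate,
            }
        features.append(_feature(t.geometry, props))
    Path(path).write_text(json.dumps(_collection(features, crs)))


def read_tracts_geojson(path) -> tuple[list[TractRecord], str]:
    """Read a tract FeatureCollection back into TractRecords.

    Returns ``(records, crs_name)``. Both the record dialect written by
    :func:`write_tracts_geojson` and a plain layer with a ``geoid`` (or
    ``base_id``) property are accepted.
    """
    doc = json.loads(Path(path).read_text())
    crs = doc.get("crs", {}).get("properties", {}).get("name", "")
    records = []
    for feat in doc["features"]:
        props = feat.get("properties", {})
        geoid = props.get("geoid") or props.get("base_id")
        rate = props.get("outcome_rate")
        records.append(
            TractRecord(
                geoid=str(geoid),
                name=props.get("name"),
                geometry=shape(feat["geometry"]) if feat.get("geometry") else None,
                population=int(props.get("population", 0)),
                outcome_rate=float(rate) if rate is not None else None,
            )
        )
    return records, crs


def write_boundary_geojson(path, boundary, crs: str) -> None:
    Path(path).write_text(
        json.dumps(_collection([_feature(boundary, {"role": "boundary"})], crs))
    )


def read_boundary_geojson(path):
    doc = json.loads(Path(path).read_text())
    return shape(doc["features"][0]["geometry"])


def write_outcomes_csv(path, tracts: Sequence[TractRecord]) -> None:
    pd.DataFrame(
        {
            "geoid": [t.geoid for t in tracts],
            "population": [t.population for t in tracts],
            "outcome_rate": [t.outcome_rate for t in tracts],
        }
    ).to_csv(path, index=False)


def read_outcomes_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"geoid": str})


def join_attributes(
    tracts: Sequence[TractRecord], attrs: pd.DataFrame
) -> list[TractRecord]:
    """Join population/outcome attributes onto geometry-only records by geoid."""
    table = attrs.set_index("geoid")
    out = []
    for t in tracts:
        if t.geoid in table.index:
            row = table.loc[t.geoid]
            rate = row.get("outcome_rate")
            out.append(
                TractRecord(
                    geoid=t.geoid,
                    name=t.name,
                    geometry=t.geometry,
                    population=int(row.get("population", t.population)),
                    outcome_rate=float(rate) if pd.notna(rate) else None,
                )
            )
        else:
            out.append(t)
    return out


def write_manifest(path, config, extra: Optional[dict] = None) -> None:
    """Record the generating configuration (and any run metadata) as YAML."""
    doc = {"config": {k: _plain(v) for k, v in vars(config).items()}}
    if extra:
        doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_manifest(path) -> dict:
    return yaml.safe_load(Path(path).read_text())


def _plain(v):
    if isinstance(v, tuple):
        return list(v)
    return v
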