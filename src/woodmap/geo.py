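"""GeoJSON polygon IO and areal bookkeeping.

Boundaries are exchanged as GeoJSON FeatureCollections in a projected,
metric CRS (for Great Britain, the national grid).  Internally a set of
boundaries is just ``{code: shapely geometry}``; areas are reported in km².
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

M2_PER_KM2 = 1e6


def read_polygons(path, code_property: str = "lsoa") -> dict[str, BaseGeometry]:
    """Read a GeoJSON FeatureCollection into ``{code: geometry}``."""
    with open(path) as fh:
        gj = json.load(fh)
    out = {}
    for feature in gj["features"]:
        code = feature["properties"][code_property]
        if code in out:
            raise ValueError(f"duplicate geography code in GeoJSON: {code}")
        out[code] = shape(feature["geometry"])
    return out


def write_polygons(
    polygons: dict[str, BaseGeometry],
    path,
    code_property: str = "lsoa",
    extra_properties: pd.DataFrame | None = None,
) -> None:
    """Write ``{code: geometry}`` as a GeoJSON FeatureCollection."""
    features = []
    for code in sorted(polygons):
        props = {code_property: code}
        if extra_properties is not None and code in extra_properties.index:
            props.update(extra_properties.loc[code].to_dict())
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": mapping(polygons[code]),
            }
        )
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def polygon_areas_km2(polygons: dict[str, BaseGeometry]) -> pd.Series:
    """Planar areas in km², assuming coordinates in metres."""
    return pd.Series(
        {code: geom.area / M2_PER_KM2 for code, geom in polygons.items()},
        name="area_km2",
    ).rename_axis("geography")
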