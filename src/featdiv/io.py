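"""Readers and writers for species -> feature tables (TSV and JSON)."""

from __future__ import annotations

import json
import os

import pandas as pd

from .fd import FeatureAssignment

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_feature_json",
    "write_feature_json",
]


def read_feature_table(path: str | os.PathLike) -> FeatureAssignment:
    """TSV with columns ``species``, ``feature`` and optional ``richness``.

    A row with an empty ``feature`` field declares a species with no features.
    Richness defaults to 1 when the column is absent or a cell is empty.
    """
    df = pd.read_csv(path, sep="\t", dtype={"species": str, "feature": str})
    if "species" not in df.columns or "feature" not in df.columns:
        raise ValueError("feature table needs 'species' and 'feature' columns")
    features_of: dict[str, set[str]] = {}
    richness: dict[str, float] = {}
    has_rich = "richness" in df.columns
    for _, row in df.iterrows():
        sp = row["species"]
        features_of.setdefault(sp, set())
        feat = row["feature"]
        if pd.isna(feat) or feat == "":
            continue
        features_of[sp].add(feat)
        if has_rich and not pd.isna(row["richness"]):
            richness[feat] = float(row["richness"])
    return FeatureAssignment.build(features_of, richness)


def write_feature_table(assignment: FeatureAssignment, path: str | os.PathLike) -> None:
    rows = []
    for sp in assignment.species:
        feats = sorted(assignment.features_of[sp])
        if not feats:
            rows.append({"species": sp, "feature": "", "richness": ""})
        for f in feats:
            rows.append({"species": sp, "feature": f, "richness": assignment.richness[f]})
    pd.DataFrame(rows, columns=["species", "feature", "richness"]).to_csv(
        path, sep="\t", index=False
    )


def read_feature_json(path: str | os.PathLike) -> FeatureAssignment:
    """JSON object ``{"features_of": {species: [features]},
    "richness": {feature: value}}``; ``richness`` optional."""
    with open(path) as fh:
        obj = json.load(fh)
    if "features_of" not in obj:
        raise ValueError("feature JSON needs a 'features_of' object")
    return FeatureAssignment.build(obj["features_of"], obj.get("richness"))


def write_feature_json(assignment: FeatureAssignment, path: str | os.PathLike) -> None:
    obj = {
        "features_of": {sp: sorted(assignment.features_of[sp]) for sp in assignment.species},
        "richness": dict(sorted(assignment.richness.items())),
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=False)
        fh.write("\n")
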