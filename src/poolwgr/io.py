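"""Plain-text file formats for genotypes, maps, phenotypes and results.

Genotype file: CSV/TSV, one row per line; columns ``line_id``, ``population``,
then one integer column per marker ({0,1,2}, ``NA`` for missing); the header
row carries the marker ids.  Map file: TSV with columns ``marker``,
``chromosome``, ``position_cM``.  Phenotype file: CSV with columns
``line_id``, ``population``, ``value``.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .popgen import GeneticMap, MarkerData

__all__ = [
    "read_map",
    "write_map",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "write_manifest",
]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep=_sep(path))
    required = {"marker", "chromosome", "position_cM"}
    if not required.issubset(df.columns):
        raise ValueError(f"map file {path} must have columns {sorted(required)}")
    return GeneticMap(
        df["marker"].to_numpy(object),
        df["chromosome"].to_numpy(np.int64),
        df["position_cM"].to_numpy(float),
    )


def write_map(map: GeneticMap, path) -> None:
    map.to_frame().to_csv(path, sep=_sep(path), index=False)


def read_genotypes(path, map_path=None) -> MarkerData:
    """Read a genotype table; entries outside {0, 1, 2, NA} raise a parse error.

    Without a map file, a trivial single-chromosome map with 1-cM spacing is
    attached (sufficient for analyses that do not use map positions).
    """
    df = pd.read_csv(path, sep=_sep(path), dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] <= 2:
        raise ValueError(f"genotype file {path} is empty")
    if list(df.columns[:2]) != ["line_id", "population"]:
        raise ValueError("first two columns must be 'line_id' and 'population'")
    marker_ids = np.array(df.columns[2:], dtype=object)
    raw = df.iloc[:, 2:].to_numpy(str)
    geno = np.empty(raw.shape, dtype=float)
    valid = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan, "": np.nan}
    for (i, j), v in np.ndenumerate(raw):
        if v not in valid:
            raise ValueError(
                f"invalid genotype {v!r} at line {df['line_id'].iloc[i]!r}, "
                f"marker {marker_ids[j]!r} (row {i + 2} of {path})"
            )
        geno[i, j] = valid[v]
    if map_path is not None:
        gmap = read_map(map_path)
        if gmap.n_markers != marker_ids.size or np.any(gmap.marker_ids != marker_ids):
            raise ValueError("map markers do not match genotype columns")
    else:
        gmap = GeneticMap(
            marker_ids,
            np.ones(marker_ids.size, dtype=np.int64),
            np.arange(marker_ids.size, dtype=float),
        )
    return MarkerData(
        df["line_id"].to_numpy(object),
        df["population"].to_numpy(np.int64),
        geno,
        gmap,
    )


def write_genotypes(data: MarkerData, path) -> None:
    g = data.genotypes
    cells = np.where(
        np.isnan(g), "NA", np.char.mod("%d", np.nan_to_num(g).astype(np.int64))
    )
    if not np.all(np.isnan(g) | (g == np.round(g))):
        raise ValueError("cannot write non-integer (imputed) genotypes to the count format")
    out = pd.DataFrame(cells, columns=data.map.marker_ids)
    out.insert(0, "population", data.population_labels)
    out.insert(0, "line_id", data.line_ids)
    out.to_csv(path, sep=_sep(path), index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_sep(path))
    required = {"line_id", "population", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"phenotype file {path} must have columns {sorted(required)}")
    return df


def write_phenotypes(line_ids, population_labels, values, path) -> None:
    pd.DataFrame(
        {"line_id": line_ids, "population": population_labels, "value": values}
    ).to_csv(path, sep=_sep(path), index=False)


def write_manifest(run_dir, manifest: dict) -> None:
    Path(run_dir).mkdir(parents=True, exist_ok=True)
    with open(Path(run_dir) / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
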