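"""Plain-text persistence for cohorts, connectomes and maps.

Matrices are written as comma-delimited text (one file per subject),
cohort metadata as a CSV with fixed column names (id, age, sex,
education_years, domain, group, expertise_score), connectomes as a
weight matrix plus a coordinate/hub CSV, and regional maps as two-column
(region_label, value) CSVs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix, RegionalMap
from .connectome import StructuralConnectome
from .cohort import Cohort, Subject

METADATA_COLUMNS = ["id", "age", "sex", "education_years", "domain", "group",
                    "expertise_score"]


def save_cohort(cohort: Cohort, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.metadata().to_csv(directory / "metadata.csv", index=False)
    for subj, mat in zip(cohort.subjects, cohort.matrices):
        np.savetxt(directory / f"{subj.id}.csv", mat.values, delimiter=",")


def load_cohort(directory) -> Cohort:
    directory = Path(directory)
    meta = pd.read_csv(directory / "metadata.csv")
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValueError(f"metadata.csv missing columns: {sorted(missing)}")
    subjects, matrices = [], []
    for _, row in meta.iterrows():
        subjects.append(Subject(
            id=str(row["id"]), age=float(row["age"]), sex=str(row["sex"]),
            education=float(row["education_years"]), domain=str(row["domain"]),
            group=str(row["group"]),
            expertise_score=float(row["expertise_score"]), seed=0,
        ))
        vals = np.loadtxt(directory / f"{row['id']}.csv", delimiter=",")
        matrices.append(ConnectivityMatrix(vals, "correlation"))
    return Cohort(subjects, matrices, {"source": str(directory)})


def save_connectome(connectome: StructuralConnectome, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / "weights.csv", connectome.weights, delimiter=",")
    pd.DataFrame({
        "region_label": connectome.region_labels,
        "x": connectome.coordinates[:, 0],
        "y": connectome.coordinates[:, 1],
        "z": connectome.coordinates[:, 2],
        "is_hub": connectome.hub_mask.astype(int),
    }).to_csv(directory / "regions.csv", index=False)


def load_connectome(directory) -> StructuralConnectome:
    directory = Path(directory)
    weights = np.loadtxt(directory / "weights.csv", delimiter=",")
    regions = pd.read_csv(directory / "regions.csv")
    return StructuralConnectome(
        weights,
        regions[["x", "y", "z"]].to_numpy(float),
        regions["is_hub"].to_numpy(bool),
        [str(s) for s in regions["region_label"]],
    )


def save_map(regional_map: RegionalMap, path) -> None:
    pd.DataFrame({
        "region_label": regional_map.region_labels,
        "value": regional_map.values,
    }).to_csv(path, index=False)


def load_map(path, name: str = "") -> RegionalMap:
    df = pd.read_csv(path)
    return RegionalMap(df["value"].to_numpy(float), name or Path(path).stem,
                       [str(s) for s in df["region_label"]])
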