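"""Plain-text readers and writers for the pipeline's tabular interchange.

All tables are TSV with the first column holding the feature or sample id;
genus lists are one genus per line with an optional ``kingdom=`` annotation;
ground truth and reports are JSON.  Numeric report output is rounded to 10
significant digits so reruns diff cleanly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from cfrnaflow.microbes import GenusTable, ContaminationResources


def write_counts(counts: pd.DataFrame, path: str | Path,
                 id_label: str = "feature_id") -> None:
    out = counts.copy()
    out.index.name = id_label
    out.to_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    out = samples.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_sample_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_genus_table(table: GenusTable, path: str | Path) -> None:
    out = table.counts.copy()
    out.insert(0, "kingdom", table.kingdoms.loc[out.index])
    out.index.name = "genus"
    out.to_csv(path, sep="\t")


def read_genus_table(path: str | Path, pipeline: str) -> GenusTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "kingdom" not in df.columns:
        raise ValueError(f"{path}: genus table needs a 'kingdom' column")
    kingdoms = df["kingdom"]
    counts = df.drop(columns=["kingdom"]).astype(int)
    return GenusTable(counts=counts, kingdoms=kingdoms, pipeline=pipeline)


def write_genus_list(genera: set[str] | list[str], path: str | Path,
                     kingdoms: dict[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for g in sorted(genera):
            if kingdoms and g in kingdoms:
                fh.write(f"{g}\tkingdom={kingdoms[g]}\n")
            else:
                fh.write(f"{g}\n")


def read_genus_list(path: str | Path) -> set[str]:
    genera = set()
    with open(path) as fh:
        for line in fh:
            name = line.split("\t")[0].strip()
            if name:
                genera.add(name)
    return genera


def write_resources(resources: ContaminationResources,
                    directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    profiles = resources.control_profiles.copy()
    profiles.index.name = "genus"
    profiles.to_csv(directory / "control_profiles.tsv", sep="\t")
    with open(directory / "control_types.tsv", "w") as fh:
        fh.write("control_id\tis_ecoli\n")
        for cid, flag in resources.control_is_ecoli.items():
            fh.write(f"{cid}\t{int(flag)}\n")
    write_genus_list(resources.lab_contaminants, directory / "lab.txt")
    write_genus_list(resources.skin_genera, directory / "skin.txt")
    write_genus_list(resources.nonhuman_host_viruses, directory / "vhost.txt")


def read_resources(directory: str | Path) -> ContaminationResources:
    directory = Path(directory)
    profiles = pd.read_csv(directory / "control_profiles.tsv", sep="\t",
                           index_col=0)
    types = pd.read_csv(directory / "control_types.tsv", sep="\t",
                        index_col=0)
    return ContaminationResources(
        control_profiles=profiles,
        control_is_ecoli={str(c): bool(v)
                          for c, v in types["is_ecoli"].items()},
        lab_contaminants=read_genus_list(directory / "lab.txt"),
        skin_genera=read_genus_list(directory / "skin.txt"),
        nonhuman_host_viruses=read_genus_list(directory / "vhost.txt"),
    )


def _round_floats(obj, sig: int = 10):
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), sig)
    return obj


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_round_floats(obj), fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
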