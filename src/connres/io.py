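"""Plain-text readers/writers for every artifact the pipeline exchanges.

Connectomes are delimited matrices with node ids in the header, partitions
and subject tables are TSV, lesion libraries are flat region-id lists with
a JSON provenance sidecar, and reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core import ModulePartition, WeightedConnectome
from .lesion_mapping import LesionRegionSet
from .synthetic_cohort import SubjectRecord, SyntheticCohort

__all__ = [
    "write_connectome",
    "read_connectome",
    "write_partition",
    "read_partition",
    "write_lesion_library",
    "read_lesion_library",
    "subjects_to_frame",
    "write_cohort",
    "read_timeseries",
]


def write_connectome(conn: WeightedConnectome, path: str | Path) -> None:
    df = pd.DataFrame(conn.weights, index=conn.node_ids, columns=conn.node_ids)
    with open(path, "w") as fh:
        if conn.removed_nodes:
            ledger = ";".join(f"{rid}:{reason}" for rid, reason in conn.removed_nodes)
            fh.write(f"# removed {ledger}\n")
        df.to_csv(fh, sep="\t", float_format="%.10g")


def read_connectome(path: str | Path) -> WeightedConnectome:
    removed: tuple = ()
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# removed "):
            entries = first[len("# removed "):].strip()
            removed = tuple(
                tuple(item.split(":", 1)) for item in entries.split(";") if item
            )
            df = pd.read_csv(fh, sep="\t", index_col=0)
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col=0)
    return WeightedConnectome(
        node_ids=tuple(str(c) for c in df.columns),
        weights=df.to_numpy(dtype=float),
        removed_nodes=removed,
    )


def write_partition(partition: ModulePartition, path: str | Path) -> None:
    pd.DataFrame(
        {"node_id": partition.node_ids, "module_id": partition.module_ids}
    ).to_csv(path, sep="\t", index=False)


def read_partition(path: str | Path) -> ModulePartition:
    df = pd.read_csv(path, sep="\t")
    return ModulePartition(
        node_ids=tuple(df["node_id"].astype(str)),
        module_ids=df["module_id"].to_numpy(dtype=int),
    )


def write_lesion_library(
    library: Sequence[LesionRegionSet], directory: str | Path
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lines = []
    sidecar = []
    for mask in library:
        regions = sorted(mask.regions)
        lines.append("\t".join([mask.mask_id, *regions]))
        sidecar.append(
            {
                "mask_id": mask.mask_id,
                "regions": regions,
                "overlap_fraction": dict(mask.overlap_fraction),
                "source": mask.source,
            }
        )
    (directory / "lesion_library.txt").write_text("\n".join(lines) + "\n")
    (directory / "lesion_library.json").write_text(json.dumps(sidecar, indent=1))


def read_lesion_library(directory: str | Path) -> list[LesionRegionSet]:
    directory = Path(directory)
    sidecar = directory / "lesion_library.json"
    if sidecar.exists():
        data = json.loads(sidecar.read_text())
        return [
            LesionRegionSet(
                mask_id=d["mask_id"],
                regions=frozenset(d["regions"]),
                overlap_fraction=d.get("overlap_fraction", {}),
                source=d.get("source", "clinical_mask"),
            )
            for d in data
        ]
    out = []
    for line in (directory / "lesion_library.txt").read_text().splitlines():
        fields = line.strip().split("\t")
        if not fields or not fields[0]:
            continue
        out.append(
            LesionRegionSet(
                mask_id=fields[0],
                regions=frozenset(fields[1:]),
                overlap_fraction={r: 1.0 for r in fields[1:]},
                source="clinical_mask",
            )
        )
    return out


def subjects_to_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for rec in subjects:
        rows.append(
            {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "timepoints": ",".join(rec.timepoints),
                "age": rec.age,
                "sex": rec.sex,
                "nihss": rec.nihss,
                "lesion_size": rec.lesion_size,
                "lesion_type": rec.lesion_type,
                "lesion_location": rec.lesion_location,
                "primary_removed_regions": ",".join(
                    sorted(rec.primary_removed_regions)
                ),
            }
        )
    return pd.DataFrame(rows)


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> None:
    """Write subject table, connectomes, partition and lesion library."""
    directory = Path(directory)
    (directory / "connectomes").mkdir(parents=True, exist_ok=True)
    subjects_to_frame(cohort.subjects).to_csv(
        directory / "subjects.tsv", sep="\t", index=False
    )
    write_partition(cohort.partition, directory / "partition.tsv")
    write_lesion_library(cohort.lesion_library, directory)
    for (sid, tp), conn in cohort.connectomes.items():
        write_connectome(conn, directory / "connectomes" / f"{sid}_{tp}.tsv")
    (directory / "hub_nodes.txt").write_text("\n".join(cohort.hub_nodes) + "\n")


def read_timeseries(path: str | Path, tr_seconds: float):
    """Region-by-time TSV (first column region_id) -> RegionTimeSeries."""
    from .preprocessing import RegionTimeSeries

    df = pd.read_csv(path, sep="\t", index_col=0)
    return RegionTimeSeries(
        region_ids=tuple(str(i) for i in df.index),
        samples=df.to_numpy(dtype=float),
        tr_seconds=tr_seconds,
    )
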