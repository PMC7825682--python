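"""Patient CSV dialect and graph/partition exports.

One row per patient; canonical columns are ``id, gender, age,
systolic_bp, diastolic_bp, hbp_flag, bmi, neck_circumference, ess,
ahi_before, ahi_after, osa_label``. Optional fields are left empty;
unknown columns are ignored. Rows violating record invariants are
skipped and logged with their row number — there is no imputation.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import networkx as nx
import pandas as pd

from .cohort import PatientRecord
from .communities import CommunityPartition, LayoutResult

__all__ = [
    "read_patients",
    "write_patients",
    "write_partition_csv",
    "write_layout_csv",
    "write_edgelist_csv",
    "export_graph",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "id",
    "gender",
    "age",
    "bmi",
    "neck_circumference",
    "ess",
    "ahi_before",
)
OPTIONAL_COLUMNS = (
    "systolic_bp",
    "diastolic_bp",
    "hbp_flag",
    "ahi_after",
    "osa_label",
)

PathLike = Union[str, Path]


def _parse_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in ("true", "1", "yes"):
        return True
    if s in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot parse boolean {value!r}")


def _parse_float(value) -> Optional[float]:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    return float(value)


def read_patients(path: PathLike) -> list[PatientRecord]:
    """Read and validate patient records; invalid rows are skipped and logged.

    Raises ``ValueError`` when the header misses required columns.
    Duplicate ids are rejected.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"malformed header: missing column(s) {missing}")
    records: list[PatientRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rownum = i + 2  # header is line 1
        try:
            pid = str(row["id"])
            if pid in seen:
                raise ValueError(f"duplicate id {pid!r}")
            rec = PatientRecord(
                id=pid,
                gender=str(row["gender"]).strip().lower(),
                age=float(row["age"]),
                bmi=float(row["bmi"]),
                neck_circumference=float(row["neck_circumference"]),
                ess=int(float(row["ess"])),
                ahi_before=float(row["ahi_before"]),
                systolic_bp=_parse_float(row.get("systolic_bp")),
                diastolic_bp=_parse_float(row.get("diastolic_bp")),
                hbp_flag=_parse_bool(row.get("hbp_flag")),
                ahi_after=_parse_float(row.get("ahi_after")),
                osa_label=_parse_bool(row.get("osa_label")),
            )
        except (ValueError, TypeError) as err:
            logger.warning("skipping row %d: %s", rownum, err)
            continue
        seen.add(pid)
        records.append(rec)
    return records


def write_patients(records: Iterable[PatientRecord], path: PathLike) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "id": r.id,
                "gender": r.gender,
                "age": r.age,
                "systolic_bp": r.systolic_bp,
                "diastolic_bp": r.diastolic_bp,
                "hbp_flag": r.hbp_flag,
                "bmi": r.bmi,
                "neck_circumference": r.neck_circumference,
                "ess": r.ess,
                "ahi_before": r.ahi_before,
                "ahi_after": r.ahi_after,
                "osa_label": r.osa_label,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_partition_csv(partition: CommunityPartition, path: PathLike) -> None:
    pd.DataFrame(
        sorted(partition.assignment.items()), columns=["id", "community"]
    ).to_csv(path, index=False)


def write_layout_csv(layout: LayoutResult, path: PathLike) -> None:
    rows = [(v, x, y) for v, (x, y) in sorted(layout.coordinates.items())]
    pd.DataFrame(rows, columns=["id", "x", "y"]).to_csv(path, index=False)


def write_edgelist_csv(G: nx.Graph, path: PathLike) -> None:
    rows = sorted(
        (min(u, v), max(u, v), d.get("weight", 1)) for u, v, d in G.edges(data=True)
    )
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, index=False
    )


def export_graph(
    G: nx.Graph,
    path: PathLike,
    partition: Optional[CommunityPartition] = None,
    layout: Optional[LayoutResult] = None,
) -> None:
    """Write GEXF or GraphML (by extension) with community/layout attributes."""
    H = G.copy()
    if partition is not None:
        nx.set_node_attributes(H, partition.assignment, "community")
    if layout is not None:
        nx.set_node_attributes(
            H, {v: float(x) for v, (x, y) in layout.coordinates.items()}, "x"
        )
        nx.set_node_attributes(
            H, {v: float(y) for v, (x, y) in layout.coordinates.items()}, "y"
        )
    path = Path(path)
    if path.suffix == ".gexf":
        nx.write_gexf(H, path)
    elif path.suffix == ".graphml":
        nx.write_graphml(H, path)
    else:
        raise ValueError(f"unsupported graph format {path.suffix!r}")
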