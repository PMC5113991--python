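"""CSV / YAML interchange for measurements, permeability tables and contact graphs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .morphometry import ContactEdge, ContactGraph
from .series import BathSchedule, MeasurementSeries
from .solutions import SOLUTION_A, BathPair, Solution

__all__ = [
    "MEASUREMENT_COLUMNS",
    "read_measurements",
    "write_measurements",
    "write_contact_graph",
    "read_contact_graph",
    "read_schedule_config",
]

MEASUREMENT_COLUMNS = ("filter_id", "role", "time_min", "resistance_ohm_cm2",
                       "potential_mV")

#: insert growth area of a 12-mm Transwell, cm^2; used to area-normalize raw ohms
DEFAULT_INSERT_AREA = 1.12


def read_measurements(path: str | Path, insert_area: float = DEFAULT_INSERT_AREA
                      ) -> tuple[dict[str, MeasurementSeries], MeasurementSeries]:
    """Read a raw-measurement CSV into (sample series by filter id, blank series).

    Expected columns: ``filter_id, role, time_min, potential_mV`` and either
    ``resistance_ohm_cm2`` (area-normalized) or ``resistance_ohm`` (raw ohms,
    converted with ``insert_area``).  ``role`` is ``sample`` or ``blank``;
    exactly one blank filter is expected per file.
    """
    df = pd.read_csv(path)
    required = {"filter_id", "role", "time_min", "potential_mV"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if "resistance_ohm_cm2" in df.columns:
        resistance = df["resistance_ohm_cm2"].to_numpy(float)
    elif "resistance_ohm" in df.columns:
        resistance = df["resistance_ohm"].to_numpy(float) * insert_area
    else:
        raise ValueError(f"{path}: missing column resistance_ohm_cm2 (or resistance_ohm)")
    df = df.assign(_r=resistance)

    bad_roles = set(df["role"]) - {"sample", "blank"}
    if bad_roles:
        raise ValueError(f"{path}: unknown role(s) {sorted(bad_roles)}")

    def series(sub: pd.DataFrame, label: str) -> MeasurementSeries:
        sub = sub.sort_values("time_min")
        return MeasurementSeries(sub["time_min"].to_numpy(float),
                                 sub["_r"].to_numpy(float),
                                 sub["potential_mV"].to_numpy(float), label=label)

    blanks = df[df["role"] == "blank"]
    blank_ids = sorted(set(blanks["filter_id"]))
    if len(blank_ids) != 1:
        raise ValueError(f"{path}: expected exactly one blank filter, found {blank_ids}")
    blank = series(blanks, str(blank_ids[0]))
    samples = {
        str(fid): series(sub, str(fid))
        for fid, sub in df[df["role"] == "sample"].groupby("filter_id")
    }
    if not samples:
        raise ValueError(f"{path}: no sample filters")
    return samples, blank


def write_measurements(path: str | Path,
                       series_by_filter: dict[str, tuple[str, MeasurementSeries]]) -> None:
    """Write series as the measurement CSV dialect; values are {id: (role, series)}."""
    frames = []
    for fid, (role, s) in series_by_filter.items():
        frames.append(pd.DataFrame({
            "filter_id": fid, "role": role, "time_min": s.time,
            "resistance_ohm_cm2": s.resistance, "potential_mV": s.potential,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# contact graphs


def write_contact_graph(path: str | Path, graph: ContactGraph) -> None:
    """Long-format CSV: one row per polyline point, field extent in a header comment."""
    rows = []
    for eid, e in enumerate(graph.edges):
        for k, (x, y) in enumerate(e.polyline):
            rows.append((eid, e.v1, e.v2, k, x, y))
    df = pd.DataFrame(rows, columns=["edge_id", "v1", "v2", "point_index", "x_um", "y_um"])
    extent = " ".join(f"{v:.6f}" for v in graph.field_extent)
    with open(path, "w") as fh:
        fh.write(f"# field_extent {extent}\n")
        df.to_csv(fh, index=False)


def read_contact_graph(path: str | Path) -> ContactGraph:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# field_extent"):
            raise ValueError(f"{path}: missing '# field_extent' header line")
        extent = tuple(float(v) for v in header.split()[2:])
        df = pd.read_csv(fh)
    vertices: dict[int, tuple[float, float]] = {}
    edges = []
    for _, sub in df.groupby("edge_id"):
        sub = sub.sort_values("point_index")
        poly = sub[["x_um", "y_um"]].to_numpy(float)
        v1, v2 = int(sub["v1"].iloc[0]), int(sub["v2"].iloc[0])
        vertices.setdefault(v1, (float(poly[0, 0]), float(poly[0, 1])))
        vertices.setdefault(v2, (float(poly[-1, 0]), float(poly[-1, 1])))
        edges.append(ContactEdge(v1, v2, poly))
    return ContactGraph(vertices=vertices, edges=edges, field_extent=extent)


# ---------------------------------------------------------------------------
# declarative schedule config


def _solution_from_config(name: str, spec: dict | str,
                          solutions: dict[str, Solution]) -> Solution:
    if isinstance(spec, str):
        if spec in solutions:
            return solutions[spec]
        raise ValueError(f"unknown solution reference {spec!r}")
    known = {f.name for f in Solution.__dataclass_fields__.values()} - {"name"}
    unknown = set(spec) - known
    if unknown:
        raise ValueError(f"solution {name!r}: unknown key(s) {sorted(unknown)}")
    return Solution(name=name, **{k: float(v) for k, v in spec.items()})


def read_schedule_config(path: str | Path) -> BathSchedule:
    """Parse a YAML bath-schedule config.

    Layout::

        solutions:            # optional custom solutions (mM per solute)
          apical_start: {nacl: 70, kcl: 5, mgcl2: 1, cacl2: 1, glucose: 5, hepes_naoh: 10}
        condition:
          apical: apical_start        # a name defined above, or 'solution_A'
          basal: solution_A
          switches:                   # optional
            - {time_min: 120, apical: apical_iso}

    A switch lists the replaced side(s); the other side carries over.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "condition" not in cfg:
        raise ValueError(f"{path}: expected a mapping with a 'condition' section")
    unknown = set(cfg) - {"solutions", "condition"}
    if unknown:
        raise ValueError(f"{path}: unknown top-level key(s) {sorted(unknown)}")

    solutions: dict[str, Solution] = {"solution_A": SOLUTION_A}
    for name, spec in (cfg.get("solutions") or {}).items():
        solutions[name] = _solution_from_config(name, spec, solutions)

    cond = cfg["condition"]
    unknown = set(cond) - {"apical", "basal", "switches"}
    if unknown:
        raise ValueError(f"{path}: unknown condition key(s) {sorted(unknown)}")
    apical = _solution_from_config("apical", cond["apical"], solutions)
    basal = _solution_from_config("basal", cond["basal"], solutions)

    switches = []
    current = BathPair(apical, basal)
    for sw in cond.get("switches") or []:
        t = float(sw["time_min"])
        new_apical = (_solution_from_config("apical", sw["apical"], solutions)
                      if "apical" in sw else current.apical)
        new_basal = (_solution_from_config("basal", sw["basal"], solutions)
                     if "basal" in sw else current.basal)
        current = BathPair(new_apical, new_basal)
        switches.append((t, current))
    return BathSchedule(BathPair(apical, basal), switches)
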