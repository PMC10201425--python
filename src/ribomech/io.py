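"""Readers and writers for the package's file dialects.

Structures: multi-model PDB (v3.3 fixed-width ATOM/HETATM subset, B-factor
column retained, 1-based residue numbering) through biotite, plus a plain
XYZ alternative with roles supplied by a separate JSON atom map. Tables:
comma-separated CSV with mandatory headers ('.' decimal, UTF-8, no index
column). Results: JSON with declared units. All writers are deterministic;
all readers reject malformed input rather than coercing it.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .afe import LambdaSeries
from .constants import DEFAULT_TEMPERATURE
from .fes import FreeEnergySurface, UmbrellaWindow, UmbrellaWindowSet
from .trajectory import AtomMap, Frame, Topology, Trajectory

logger = logging.getLogger(__name__)

UNITS = {
    "energy": "kcal/mol",
    "distance": "angstrom",
    "angle": "degree",
    "rate": "1/min",
    "temperature": "K",
}

WINDOW_COLUMNS = ["window_id", "center_pt", "center_mt", "k_pt", "k_mt", "xi_pt", "xi_mt"]
LAMBDA_COLUMNS = ["lam", "sample_index", "dudl"]


class FormatError(ValueError):
    """Input file violates the declared dialect."""


class RunConfig(BaseModel):
    """Serializable run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE
    units: dict[str, str] = Field(default_factory=lambda: dict(UNITS))
    stages: dict[str, dict[str, Any]] = Field(default_factory=dict)
    outdir: str = "."

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate_json(Path(path).read_text())

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")


# ---------------------------------------------------------------------------
# structures


def _validate_pdb_lines(path: Path) -> None:
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line.rstrip()) < 66:
                raise FormatError(
                    f"{path.name}: malformed fixed-width ATOM record at line {lineno} "
                    f"(need at least 66 columns, got {len(line.rstrip())})"
                )


def read_structure(path: str | Path, model_policy: str = "all") -> Trajectory:
    """Read a (multi-model) PDB file into a :class:`Trajectory`.

    MODEL/ENDMDL delimit frames; 1-based residue numbering and the B-factor
    column are preserved (B-factors taken from the first model). Alternate
    locations keep the blank/'A' conformer, logging the number dropped.
    """
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such structure file: {path}")
    if model_policy not in ("first", "all"):
        raise ValueError(f"unknown model policy {model_policy!r}")
    _validate_pdb_lines(path)

    n_altloc = sum(
        1
        for line in path.read_text().splitlines()
        if line.startswith(("ATOM", "HETATM")) and line[16] not in (" ", "A")
    )
    if n_altloc:
        logger.info("dropping %d non-'A' altloc records", n_altloc)

    pfile = pdb.PDBFile.read(str(path))
    try:
        stack = pdb.get_structure(pfile, altloc="first", extra_fields=["b_factor"])
    except Exception as exc:
        raise FormatError(f"{path.name}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    if stack.array_length() == 0:
        raise FormatError(f"{path.name}: zero atoms")
    if model_policy == "first":
        stack = stack[:1]

    top = Topology(
        atom_names=tuple(str(n) for n in stack.atom_name),
        residue_ids=np.asarray(stack.res_id, dtype=int),
        residue_names=tuple(str(n) for n in stack.res_name),
        elements=tuple(str(e) for e in stack.element),
    )
    bfac = None
    if "b_factor" in stack.get_annotation_categories():
        bfac = np.asarray(stack.b_factor, dtype=float)
    return Trajectory(top, np.asarray(stack.coord, dtype=float), bfactors=bfac)


def write_structure(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file (deterministic output)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = traj.n_atoms
    stack = struc.AtomArrayStack(traj.n_frames, n)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    stack.atom_name = np.array(traj.topology.atom_names)
    stack.res_id = np.asarray(traj.topology.residue_ids)
    stack.res_name = np.array(traj.topology.residue_names)
    stack.element = np.array(traj.topology.elements)
    stack.chain_id = np.full(n, "A")
    stack.hetero = np.zeros(n, dtype=bool)
    stack.set_annotation(
        "b_factor",
        np.asarray(
            traj.bfactors if traj.bfactors is not None else np.zeros(n), dtype=float
        ),
    )
    pfile = pdb.PDBFile()
    pdb.set_structure(pfile, stack)
    pfile.write(str(path))


def read_xyz(path: str | Path) -> Trajectory:
    """Read a (multi-frame) XYZ file; atom roles come from a JSON atom map.

    Atoms are addressed as residue 1..n in file order with names
    ``<element><index>``, so an accompanying atom map can reference them.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames = []
    elements: list[str] | None = None
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError as exc:
            raise FormatError(f"{path.name}: bad atom count at line {i + 1}") from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise FormatError(f"{path.name}: truncated frame starting line {i + 1}")
        els, xyz = [], []
        for j, row in enumerate(block):
            parts = row.split()
            if len(parts) < 4:
                raise FormatError(f"{path.name}: malformed line {i + 3 + j}")
            els.append(parts[0])
            xyz.append([float(v) for v in parts[1:4]])
        if elements is None:
            elements = els
        elif els != elements:
            raise FormatError(f"{path.name}: inconsistent atom order between frames")
        frames.append(xyz)
        i += 2 + n
    if not frames:
        raise FormatError(f"{path.name}: no frames")
    n = len(elements)
    top = Topology(
        atom_names=tuple(f"{e}{k + 1}" for k, e in enumerate(elements)),
        residue_ids=np.arange(1, n + 1),
        residue_names=tuple("UNK" for _ in range(n)),
        elements=tuple(elements),
    )
    return Trajectory(top, np.asarray(frames, dtype=float))


def write_xyz(traj: Trajectory, path: str | Path, comment: str = "ribomech frame") -> None:
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"{traj.n_atoms}\n{comment} {f}\n")
            for a in range(traj.n_atoms):
                x, y, z = traj.coords[f, a]
                fh.write(f"{traj.topology.elements[a]} {x:.10f} {y:.10f} {z:.10f}\n")


def read_atom_map(path: str | Path) -> AtomMap:
    return AtomMap.from_dict(json.loads(Path(path).read_text()))


def write_atom_map(amap: AtomMap, path: str | Path) -> None:
    write_json(amap.to_dict(), path)


# ---------------------------------------------------------------------------
# umbrella windows


def _require_numeric(df: pd.DataFrame, cols: list[str], name: str) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise FormatError(f"{name}: non-numeric value in column {col!r} at row {row}")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 2
            raise FormatError(f"{name}: missing value in column {col!r} at row {row}")
        df[col] = coerced
    return df


def read_windows(path: str | Path) -> UmbrellaWindowSet:
    """Read the umbrella-window CSV dialect (columns matched by name)."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in WINDOW_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    df = _require_numeric(df, [c for c in WINDOW_COLUMNS if c != "window_id"], path.name)
    if (df["k_pt"] < 0).any() or (df["k_mt"] < 0).any():
        raise FormatError(f"{path.name}: negative force constant")
    windows = []
    for wid in df["window_id"].drop_duplicates():
        sub = df[df["window_id"] == wid]
        center = sub[["center_pt", "center_mt"]].iloc[0].to_numpy(dtype=float)
        kf = sub[["k_pt", "k_mt"]].iloc[0].to_numpy(dtype=float)
        if not np.allclose(sub[["center_pt", "center_mt", "k_pt", "k_mt"]], np.concatenate([center, kf])):
            raise FormatError(f"{path.name}: inconsistent window metadata for id {wid!r}")
        windows.append(UmbrellaWindow(center, kf, sub[["xi_pt", "xi_mt"]].to_numpy(dtype=float)))
    return UmbrellaWindowSet(windows)


def write_windows(ws: UmbrellaWindowSet, path: str | Path) -> None:
    rows = []
    for i, w in enumerate(ws.windows):
        for s in w.samples:
            rows.append((i, w.center[0], w.center[1], w.kforce[0], w.kforce[1], s[0], s[1]))
    pd.DataFrame(rows, columns=WINDOW_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# lambda series


def read_lambda_series(path: str | Path, temperature: float = DEFAULT_TEMPERATURE) -> LambdaSeries:
    """Read the λ-series CSV dialect (lam, sample_index, dudl [, work_fwd, work_rev]).

    Work columns, when present, hold samples for the λᵢ→λᵢ₊₁ exchange on
    rows of λᵢ (empty on the last λ).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in LAMBDA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    df = _require_numeric(df, ["lam", "dudl"], path.name)
    lams = np.sort(df["lam"].unique())
    dudl = [df.loc[df["lam"] == l, "dudl"].to_numpy(dtype=float) for l in lams]
    work_fwd = work_rev = None
    if "work_fwd" in df.columns and "work_rev" in df.columns:
        work_fwd, work_rev = [], []
        for l in lams[:-1]:
            sub = df[df["lam"] == l]
            wf = sub["work_fwd"].dropna().to_numpy(dtype=float)
            wr = sub["work_rev"].dropna().to_numpy(dtype=float)
            if wf.size == 0 or wr.size == 0:
                work_fwd = work_rev = None
                break
            work_fwd.append(wf)
            work_rev.append(wr)
    return LambdaSeries(lams, dudl, work_fwd, work_rev, temperature=temperature)


def write_lambda_series(series: LambdaSeries, path: str | Path) -> None:
    rows = []
    for i, lam in enumerate(series.lambdas):
        wf = series.work_fwd[i] if series.work_fwd is not None and i < len(series.lambdas) - 1 else None
        wr = series.work_rev[i] if series.work_rev is not None and i < len(series.lambdas) - 1 else None
        for j, d in enumerate(series.dudl[i]):
            rows.append(
                (
                    lam,
                    j,
                    d,
                    wf[j] if wf is not None and j < len(wf) else np.nan,
                    wr[j] if wr is not None and j < len(wr) else np.nan,
                )
            )
    pd.DataFrame(rows, columns=LAMBDA_COLUMNS + ["work_fwd", "work_rev"]).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# surfaces, paths, generic JSON


def fes_to_dict(surface: FreeEnergySurface) -> dict:
    values = np.where(surface.mask, np.nan, surface.values)
    se = surface.se if surface.se is not None else np.full_like(surface.values, np.nan)
    return {
        "units": dict(UNITS),
        "temperature": surface.temperature,
        "axes": [a.tolist() for a in surface.axes],
        "values": _nan_to_none(values),
        "se": _nan_to_none(np.asarray(se, dtype=float)),
        "counts": surface.counts.tolist(),
        "mask": surface.mask.tolist(),
    }


def fes_from_dict(data: dict) -> FreeEnergySurface:
    axes = [np.asarray(a, dtype=float) for a in data["axes"]]
    shape = tuple(a.size for a in axes)
    mask = np.asarray(data["mask"], dtype=bool).reshape(shape)
    values = np.asarray(_none_to_nan(data["values"]), dtype=float).reshape(shape)
    values = np.where(mask, np.inf, values)
    se = np.asarray(_none_to_nan(data["se"]), dtype=float).reshape(shape)
    return FreeEnergySurface(
        axes=axes,
        values=values,
        counts=np.asarray(data["counts"], dtype=int).reshape(shape),
        mask=mask,
        temperature=float(data["temperature"]),
        se=se,
    )


def _nan_to_none(arr: np.ndarray):
    return [
        [None if not np.isfinite(v) else float(v) for v in row]
        for row in np.atleast_2d(arr)
    ]


def _none_to_nan(nested):
    return [[np.nan if v is None else v for v in row] for row in nested]


def write_fes(surface: FreeEnergySurface, path: str | Path) -> None:
    write_json(fes_to_dict(surface), path)


def read_fes(path: str | Path) -> FreeEnergySurface:
    return fes_from_dict(json.loads(Path(path).read_text()))


def write_json(obj: Any, path: str | Path) -> None:
    """Deterministic JSON writer: sorted keys, fixed separators, newline EOF."""
    Path(path).write_text(
        json.dumps(obj, sort_keys=True, indent=2, allow_nan=False) + "\n"
    )
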