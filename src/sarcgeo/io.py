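"""Reading and writing atomic models, particle tables and filament traces.

Conventions fixed here and used repo-wide:

* coordinates are ångström everywhere internally; nanometres appear only in
  user-facing output when explicitly requested;
* particle orientations are three Euler angles in degrees, **intrinsic Z-Y-Z**
  (the usual subtomogram-averaging convention), each normalised to (-180, 180];
* the native particle-table dialect is UTF-8 TSV with a header row and columns
  ``filament_id  segment_index  x_A  y_A  z_A  rot_deg  tilt_deg  psi_deg
  class  score`` (the last two optional); ``segment_index`` is 1-based;
* STAR tables are read through :mod:`gemmi.cif` and converted from pixels to
  ångström with a mandatory pixel size.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomModel",
    "PointSet",
    "ParticleRecord",
    "FilamentTrace",
    "LinkRecord",
    "read_structure",
    "write_structure",
    "select_atoms",
    "read_particle_table",
    "write_particle_table",
    "records_to_frame",
    "frame_to_records",
    "normalize_angle",
]

NATIVE_COLUMNS = [
    "filament_id", "segment_index", "x_A", "y_A", "z_A",
    "rot_deg", "tilt_deg", "psi_deg", "class", "score",
]
REQUIRED_COLUMNS = NATIVE_COLUMNS[:8]


def normalize_angle(a: float) -> float:
    """Map an angle in degrees to the interval (-180, 180]."""
    a = math.fmod(a, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


# ---------------------------------------------------------------------------
# atomic models
# ---------------------------------------------------------------------------

@dataclass
class AtomModel:
    """Hierarchical atomic coordinates: chains -> residues -> named atoms.

    ``atoms`` is a DataFrame with columns ``chain, resi, atom, x, y, z``
    (coordinates in Å), ordered as read.  ``chain_labels`` carries optional
    free-text annotations per chain (e.g. ``"myosin-tail-crown2"``).
    """

    atoms: pd.DataFrame
    chain_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("empty model: no atoms")
        xyz = self.atoms[["x", "y", "z"]].to_numpy(float)
        if not np.all(np.isfinite(xyz)):
            raise ValueError("non-finite atom coordinates")
        dup = self.atoms.duplicated(subset=["chain", "resi", "atom"])
        if dup.any():
            row = self.atoms[dup].iloc[0]
            raise ValueError(
                f"duplicate (chain,residue,atom) triple: "
                f"({row.chain},{row.resi},{row.atom})"
            )
        for cid, sub in self.atoms.groupby("chain", sort=False):
            resi = sub["resi"].to_numpy()
            # strictly increasing over residue boundaries
            first = resi[np.r_[True, resi[1:] != resi[:-1]]]
            if np.any(np.diff(first) <= 0):
                raise ValueError(f"residue numbering not increasing in chain {cid}")

    @property
    def chains(self) -> list[str]:
        return list(dict.fromkeys(self.atoms["chain"]))

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)


@dataclass
class PointSet:
    """Ordered labelled points (Å); order is meaningful (sequence order)."""

    ids: list[str]
    coords: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float).reshape(-1, 3)
        if len(self.ids) != len(self.coords):
            raise ValueError("ids and coords length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("PointSet ids must be unique")

    def __len__(self) -> int:
        return len(self.ids)


def _structure_to_model(st: gemmi.Structure, path: str) -> AtomModel:
    rows = []
    if len(st) == 0:
        raise ValueError(f"{path}: no models in file")
    model = st[0]
    for chain in model:
        for res in chain:
            for atom in res:
                rows.append((chain.name, res.seqid.num, atom.name,
                             atom.pos.x, atom.pos.y, atom.pos.z))
    if not rows:
        raise ValueError(f"{path}: file contains no coordinate records")
    frame = pd.DataFrame(rows, columns=["chain", "resi", "atom", "x", "y", "z"])
    return AtomModel(frame)


def read_structure(path: str | Path, format: str = "auto") -> AtomModel:
    """Read an atomic model from mmCIF or PDB.

    Parameters
    ----------
    path : path to the coordinate file.
    format : ``"mmcif"``, ``"pdb"`` or ``"auto"`` (detect from contents).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = {"auto": gemmi.CoorFormat.Detect,
           "pdb": gemmi.CoorFormat.Pdb,
           "mmcif": gemmi.CoorFormat.Mmcif}.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}; use mmcif, pdb or auto")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"{path}: parse error: {exc}") from exc
    st.setup_entities()
    return _structure_to_model(st, str(path))


def write_structure(model: AtomModel, path: str | Path, format: str = "auto") -> None:
    """Write an :class:`AtomModel` as PDB or mmCIF (by extension when auto)."""
    path = Path(path)
    if format == "auto":
        format = "mmcif" if path.suffix.lower() in {".cif", ".mmcif"} else "pdb"
    st = gemmi.Structure()
    st.name = path.stem
    md = gemmi.Model("1")
    for cid, sub in model.atoms.groupby("chain", sort=False):
        chain = gemmi.Chain(str(cid))
        for resi, res_rows in sub.groupby("resi", sort=False):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(int(resi), " ")
            for row in res_rows.itertuples():
                at = gemmi.Atom()
                at.name = row.atom
                at.element = gemmi.Element(row.atom[:1])
                at.pos = gemmi.Position(row.x, row.y, row.z)
                res.add_atom(at)
            chain.add_residue(res)
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    if format == "pdb":
        st.write_pdb(str(path))
    else:
        st.make_mmcif_document().write_file(str(path))


def select_atoms(
    model: AtomModel,
    chains: Optional[Sequence[str]] = None,
    residues: Optional[tuple[int, int] | Sequence[int]] = None,
    atom_names: Optional[Sequence[str] | str] = None,
) -> PointSet:
    """Select atoms by chain id, residue range and atom name.

    ``residues`` is either an inclusive ``(first, last)`` range or an explicit
    sequence of residue numbers.  An empty selection is returned as an empty
    PointSet, but naming a chain absent from the model is an error (listing
    the chains that do exist).
    """
    frame = model.atoms
    if chains is not None:
        missing = [c for c in chains if c not in set(frame["chain"])]
        if missing:
            raise KeyError(
                f"unknown chain(s) {missing}; model has chains {model.chains}")
        frame = frame[frame["chain"].isin(list(chains))]
    if residues is not None:
        if isinstance(residues, tuple) and len(residues) == 2:
            lo, hi = residues
            frame = frame[(frame["resi"] >= lo) & (frame["resi"] <= hi)]
        else:
            frame = frame[frame["resi"].isin(list(residues))]
    if atom_names is not None:
        if isinstance(atom_names, str):
            atom_names = [atom_names]
        frame = frame[frame["atom"].isin(list(atom_names))]
    ids = [f"{r.chain}/{r.resi}/{r.atom}" for r in frame.itertuples()]
    return PointSet(ids, frame[["x", "y", "z"]].to_numpy(float))


# ---------------------------------------------------------------------------
# particle records and filament traces
# ---------------------------------------------------------------------------

@dataclass
class ParticleRecord:
    """One filament segment: position (Å) plus intrinsic Z-Y-Z Euler angles.

    ``orientation`` is ``None`` when the source table carried no angles; the
    ``rot`` component may be NaN for tangent-derived orientations (a polyline
    tangent fixes tilt and psi but leaves the in-plane spin undefined).
    """

    filament_id: str
    segment_index: int
    position: np.ndarray
    orientation: Optional[np.ndarray] = None
    class_label: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float).reshape(3)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("particle position must be finite")
        if self.orientation is not None:
            o = np.asarray(self.orientation, float).reshape(3)
            self.orientation = np.array(
                [a if np.isnan(a) else normalize_angle(a) for a in o])

    def moved_to(self, position, orientation=None) -> "ParticleRecord":
        return replace(self, position=np.asarray(position, float),
                       orientation=orientation if orientation is not None
                       else self.orientation)


@dataclass
class FilamentTrace:
    """Ordered polyline through one filament.

    ``zward`` records the polarity convention: True means point order follows
    increasing arc length Z-ward, i.e. away from the M band.
    """

    filament_id: str
    points: np.ndarray  # (n, 3) Å
    zward: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float).reshape(-1, 3)
        if len(self.points) < 2:
            raise ValueError("trace needs at least 2 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive trace points must be distinct")

    @property
    def arclengths(self) -> np.ndarray:
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.arclengths[-1])

    def point_at(self, s: float) -> np.ndarray:
        """Linear interpolation on the polyline at arc-length position s."""
        cs = self.arclengths
        s = float(np.clip(s, 0.0, cs[-1]))
        i = int(np.searchsorted(cs, s, side="right") - 1)
        i = min(i, len(cs) - 2)
        f = (s - cs[i]) / (cs[i + 1] - cs[i])
        return (1 - f) * self.points[i] + f * self.points[i + 1]

    def tangent_at(self, s: float) -> np.ndarray:
        cs = self.arclengths
        s = float(np.clip(s, 0.0, cs[-1]))
        i = int(np.searchsorted(cs, s, side="right") - 1)
        i = min(i, len(cs) - 2)
        d = self.points[i + 1] - self.points[i]
        return d / np.linalg.norm(d)


@dataclass
class LinkRecord:
    """A thick-to-thin cMyBP-C link: pivot (C7 position) plus the ordered
    globular-domain points walking toward the thin filament (3-4 domains)."""

    pivot: np.ndarray
    domain_points: np.ndarray  # (k, 3), k >= 1
    thick_id: str = ""
    thin_id: str = ""
    angle_deg: Optional[float] = None

    def __post_init__(self) -> None:
        self.pivot = np.asarray(self.pivot, float).reshape(3)
        self.domain_points = np.asarray(self.domain_points, float).reshape(-1, 3)
        if len(self.domain_points) < 1:
            raise ValueError("link needs at least one domain point")


# ---------------------------------------------------------------------------
# particle tables
# ---------------------------------------------------------------------------

def records_to_frame(records: Iterable[ParticleRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        o = r.orientation if r.orientation is not None else (np.nan,) * 3
        rows.append((r.filament_id, r.segment_index, r.position[0],
                     r.position[1], r.position[2], o[0], o[1], o[2],
                     "" if r.class_label is None else r.class_label,
                     np.nan if r.score is None else r.score))
    return pd.DataFrame(rows, columns=NATIVE_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[ParticleRecord]:
    frame = frame.reindex(columns=NATIVE_COLUMNS)
    out = []
    for (fid, seg, x, y, z, rot, tilt, psi, cls, score) in frame.itertuples(
            index=False, name=None):
        ori = np.array([rot, tilt, psi], float)
        if np.all(np.isnan(ori)):
            ori = None
        if cls is None or (isinstance(cls, float) and np.isnan(cls)) or cls == "":
            cls = None
        else:
            cls = str(cls)
        if score is not None and isinstance(score, float) and np.isnan(score):
            score = None
        out.append(ParticleRecord(str(fid), int(seg),
                                  np.array([x, y, z], float), ori, cls, score))
    return out


def read_particle_table(
    path: str | Path,
    dialect: str = "native-tsv",
    pixel_size: Optional[float] = None,
) -> list[ParticleRecord]:
    """Read a particle table in the native TSV dialect or RELION STAR.

    STAR positions are stored in pixels; ``pixel_size`` (Å/px) is mandatory
    for that dialect.  Orientation columns are mapped to intrinsic Z-Y-Z
    unchanged; a table without orientation columns yields records whose
    orientation is marked absent.
    """
    path = Path(path)
    if dialect == "native-tsv":
        return _read_native(path)
    if dialect == "star":
        if pixel_size is None or pixel_size <= 0:
            raise ValueError("STAR import requires a positive pixel_size (Å/px)")
        return _read_star(path, pixel_size)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_native(path: Path) -> list[ParticleRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"filament_id": str, "class": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    # orientation columns may be absent as a trio
    ori_cols = {"rot_deg", "tilt_deg", "psi_deg"}
    missing_pos = [c for c in missing if c not in ori_cols]
    if missing_pos:
        raise ValueError(f"{path}: missing required column(s) {missing_pos}")
    for col in ("x_A", "y_A", "z_A"):
        bad = pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()
        if bad.any():
            raise ValueError(
                f"{path}: non-numeric value in column {col}, row "
                f"{int(np.flatnonzero(bad)[0]) + 2}")  # +2: header + 1-based
        frame[col] = pd.to_numeric(frame[col])
    return frame_to_records(frame)


def _read_star(path: Path, pixel_size: float) -> list[ParticleRecord]:
    doc = gemmi.cif.read_file(str(path))
    block = None
    for b in doc:
        if b.find_loop("_rlnCoordinateX"):
            block = b
            break
    if block is None:
        raise ValueError(f"{path}: no block with _rlnCoordinateX found")

    def col(tag):
        loop = block.find_loop(tag)
        return list(loop) if loop else None

    xs, ys, zs = col("_rlnCoordinateX"), col("_rlnCoordinateY"), col("_rlnCoordinateZ")
    if ys is None or zs is None:
        raise ValueError(f"{path}: missing _rlnCoordinateY/Z")
    rot, tilt, psi = (col("_rlnAngleRot"), col("_rlnAngleTilt"), col("_rlnAnglePsi"))
    tube = col("_rlnHelicalTubeID")
    out = []
    counters: dict[str, int] = {}
    for i in range(len(xs)):
        fid = tube[i] if tube else "star"
        counters[fid] = counters.get(fid, 0) + 1
        pos = np.array([float(xs[i]), float(ys[i]), float(zs[i])]) * pixel_size
        ori = None
        if rot is not None and tilt is not None and psi is not None:
            ori = np.array([float(rot[i]), float(tilt[i]), float(psi[i])])
        out.append(ParticleRecord(fid, counters[fid], pos, ori))
    return out


def write_particle_table(records: Iterable[ParticleRecord],
                         path: str | Path) -> None:
    """Write the native TSV dialect.  Floats use shortest round-trip repr so
    that read -> write -> read is bit-identical."""
    frame = records_to_frame(records)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(NATIVE_COLUMNS) + "\n")
        for row in frame.itertuples(index=False):
            vals = []
            for v in row:
                if isinstance(v, float):
                    vals.append("" if np.isnan(v) else repr(v))
                else:
                    vals.append(str(v))
            fh.write("\t".join(vals) + "\n")
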