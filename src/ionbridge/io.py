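"""Reading and writing of structural ensembles, mutation tables and reports.

The internal length unit is nanometres everywhere (the salt-bridge criterion
is stated in nm); PDB coordinates, which are in Ångström, are converted on
read and back-converted on write.  Frame times are in nanoseconds.

Two ensemble dialects are supported:

* ``multimodel_pdb`` — a standard PDB file with MODEL/ENDMDL blocks, one
  model per snapshot.  Parsing is delegated to :mod:`biotite`.
* ``frames_table`` — a plain TSV with columns
  ``frame, time_ns, serial, x, y, z`` (coordinates already in nm), the
  dialect the synthetic generator writes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ANGSTROM_TO_NM = 0.1
ION_RESIDUE_NAMES = frozenset({"CL", "NA"})

#: mean |coordinate| below this (nm) suggests a double Å→nm conversion
_SUSPICIOUS_COORD_MAGNITUDE_NM = 0.01

_TIME_REMARK_PREFIX = "REMARK 250 FRAME TIMES (NS):"


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


class SchemaError(ValueError):
    """Raised when a tabular input is missing required columns or rows clash."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the frame-invariant topology (coordinates live elsewhere)."""

    serial: int
    atom_name: str
    residue_name: str
    residue_seq: int
    chain_id: str
    element: str = ""

    def __post_init__(self) -> None:
        if self.serial <= 0:
            raise ValueError(f"atom serial must be positive, got {self.serial}")
        if not self.atom_name:
            raise ValueError("atom_name must be non-empty")


@dataclass
class Topology:
    """Ordered atoms plus derived residue/chain structure of one conformer set.

    Ions (residue_name CL or NA) are part of the atom list but are excluded
    from the polymer residue bookkeeping; they are surfaced via
    :attr:`ion_indices`.
    """

    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials must be unique within a topology")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def ion_indices(self) -> list[int]:
        return [
            i for i, a in enumerate(self.atoms) if a.residue_name in ION_RESIDUE_NAMES
        ]

    def polymer_indices(self) -> list[int]:
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.residue_name not in ION_RESIDUE_NAMES
        ]

    def residues(self) -> list[tuple[str, int, str]]:
        """Polymer residues as (chain_id, residue_seq, residue_name), in order."""
        seen: dict[tuple[str, int], str] = {}
        for a in self.atoms:
            if a.residue_name in ION_RESIDUE_NAMES:
                continue
            key = (a.chain_id, a.residue_seq)
            seen.setdefault(key, a.residue_name)
        return [(c, s, n) for (c, s), n in seen.items()]

    def chains(self) -> list[str]:
        """Polymer chain IDs in order of first appearance."""
        out: list[str] = []
        for a in self.atoms:
            if a.residue_name in ION_RESIDUE_NAMES:
                continue
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def chain_residues(self, chain_id: str) -> list[tuple[int, str]]:
        return [(s, n) for c, s, n in self.residues() if c == chain_id]

    def atom_index(
        self, chain_id: str, residue_seq: int, atom_name: str
    ) -> int | None:
        for i, a in enumerate(self.atoms):
            if (
                a.chain_id == chain_id
                and a.residue_seq == residue_seq
                and a.atom_name == atom_name
            ):
                return i
        return None

    def residue_atom_indices(self, chain_id: str, residue_seq: int) -> list[int]:
        return [
            i
            for i, a in enumerate(self.atoms)
            if a.chain_id == chain_id and a.residue_seq == residue_seq
        ]


@dataclass
class Trajectory:
    """F frames × A atoms × 3 coordinates in nm with strictly increasing times."""

    coords: np.ndarray  # (F, A, 3), nm
    frame_times: np.ndarray  # (F,), ns

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be (F, A, 3), got {self.coords.shape}")
        if self.frame_times.shape != (self.coords.shape[0],):
            raise ValueError("frame_times length must equal frame count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.n_frames > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame_at_time(self, time_ns: float) -> int:
        """Index of the frame nearest ``time_ns``.

        The time must fall within the trajectory span and within half the
        local frame spacing of the matched frame, so screening schedules
        cannot silently grab a distant frame.
        """
        t = self.frame_times
        if time_ns < t[0] or time_ns > t[-1]:
            raise ValueError(
                f"time {time_ns} ns outside trajectory span [{t[0]}, {t[-1]}] ns"
            )
        idx = int(np.argmin(np.abs(t - time_ns)))
        if len(t) > 1:
            spacing = np.min(np.diff(t))
            if abs(t[idx] - time_ns) > spacing / 2 + 1e-9:
                raise ValueError(
                    f"no frame within half a frame spacing of t={time_ns} ns"
                )
        return idx

    def window_mask(self, start_ns: float, end_ns: float) -> np.ndarray:
        """Boolean mask of frames with start ≤ t ≤ end (inclusive both ends)."""
        if end_ns < start_ns:
            raise ValueError("window end must be ≥ start")
        mask = (self.frame_times >= start_ns - 1e-9) & (
            self.frame_times <= end_ns + 1e-9
        )
        if not mask.any():
            raise ValueError(f"window [{start_ns}, {end_ns}] ns contains no frames")
        return mask


@dataclass(frozen=True)
class MutationEffect:
    """Denaturation-temperature shift ΔT_d (°C) for one mutated charged site."""

    chain_id: str
    residue_seq: int
    residue_name: str
    delta_td: float

    @property
    def site(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.residue_name)


# ---------------------------------------------------------------------------
# ensemble reading / writing
# ---------------------------------------------------------------------------


def _check_model_atom_counts(path: Path) -> None:
    """Pre-scan MODEL blocks so an inconsistent model can be named."""
    counts: list[tuple[int, int]] = []  # (model number, atom count)
    current: int | None = None
    n = 0
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                current = int(line.split()[1]) if len(line.split()) > 1 else (
                    len(counts) + 1
                )
                n = 0
            elif rec in ("ATOM", "HETATM"):
                n += 1
            elif rec == "ENDMDL":
                counts.append((current if current is not None else len(counts) + 1, n))
                current = None
    if current is not None:  # unterminated final model
        counts.append((current, n))
    if len(counts) > 1:
        ref = counts[0][1]
        for model_no, c in counts[1:]:
            if c != ref:
                raise FormatError(
                    f"model {model_no} has {c} atoms, expected {ref} "
                    f"(model {counts[0][0]})"
                )


def _read_time_remark(path: Path) -> np.ndarray | None:
    with open(path) as fh:
        for line in fh:
            if line.startswith(_TIME_REMARK_PREFIX):
                vals = line[len(_TIME_REMARK_PREFIX):].split()
                return np.array([float(v) for v in vals])
            if line[:6].strip() in ("ATOM", "HETATM", "MODEL"):
                break
    return None


def _read_multimodel_pdb(path: Path) -> tuple[Topology, Trajectory]:
    import biotite.structure.io.pdb as pdb

    _check_model_atom_counts(path)
    pdb_file = pdb.PDBFile.read(str(path))
    stack = pdb.get_structure(pdb_file, altloc="first")
    # biotite returns AtomArray for a single model; promote to a stack view
    if stack.coord.ndim == 2:
        coords = stack.coord[np.newaxis, :, :]
        arr = stack
    else:
        coords = stack.coord
        arr = stack[0]

    atoms = []
    for i in range(arr.array_length()):
        atoms.append(
            AtomRecord(
                serial=i + 1,
                atom_name=str(arr.atom_name[i]),
                residue_name=str(arr.res_name[i]).strip(),
                residue_seq=int(arr.res_id[i]),
                chain_id=str(arr.chain_id[i]).strip(),
                element=str(arr.element[i]).strip(),
            )
        )
    topology = Topology(atoms=atoms)

    coords_nm = coords.astype(float) * ANGSTROM_TO_NM
    if np.mean(np.abs(coords_nm)) < _SUSPICIOUS_COORD_MAGNITUDE_NM:
        warnings.warn(
            "mean |coordinate| < 0.01 nm after Å→nm conversion; input may "
            "already have been in nm",
            stacklevel=3,
        )
    times = _read_time_remark(path)
    if times is None or len(times) != coords_nm.shape[0]:
        times = np.arange(coords_nm.shape[0], dtype=float)
    return topology, Trajectory(coords=coords_nm, frame_times=times)


def _read_frames_table(
    path: Path, topology: Topology | None
) -> tuple[Topology, Trajectory]:
    df = pd.read_csv(path, sep="\t")
    required = {"frame", "time_ns", "serial", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"frames table missing columns: {sorted(missing)}")

    serials = np.sort(df.loc[df["frame"] == df["frame"].iloc[0], "serial"].to_numpy())
    frames = sorted(df["frame"].unique())
    coords = np.empty((len(frames), len(serials), 3), dtype=float)
    times = np.empty(len(frames), dtype=float)
    for fi, frame in enumerate(frames):
        sub = df[df["frame"] == frame].sort_values("serial")
        if not np.array_equal(sub["serial"].to_numpy(), serials):
            raise FormatError(f"frame {frame} has inconsistent atom serials")
        coords[fi] = sub[["x", "y", "z"]].to_numpy()
        times[fi] = sub["time_ns"].iloc[0]

    if topology is None:
        topology = Topology(
            atoms=[
                AtomRecord(
                    serial=int(s),
                    atom_name="X",
                    residue_name="UNK",
                    residue_seq=int(s),
                    chain_id="A",
                )
                for s in serials
            ]
        )
    elif topology.n_atoms != len(serials):
        raise FormatError(
            f"topology has {topology.n_atoms} atoms but frames table has "
            f"{len(serials)}"
        )
    return topology, Trajectory(coords=coords, frame_times=times)


def read_structure_ensemble(
    path: str | Path,
    format: str = "multimodel_pdb",
    topology: Topology | None = None,
) -> tuple[Topology, Trajectory]:
    """Read a snapshot ensemble into a (Topology, Trajectory) pair.

    Parameters
    ----------
    path
        Input file.
    format
        ``"multimodel_pdb"`` (Å input, converted to nm) or ``"frames_table"``
        (nm TSV written by the synthetic generator).
    topology
        Optional known topology for ``frames_table`` input, whose rows carry
        only serials and coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "multimodel_pdb":
        return _read_multimodel_pdb(path)
    if format == "frames_table":
        return _read_frames_table(path, topology)
    raise ValueError(f"unknown ensemble format: {format!r}")


def write_structure_ensemble(
    path: str | Path, topology: Topology, trajectory: Trajectory
) -> None:
    """Write a multi-model PDB (nm→Å) with a frame-time REMARK header."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    arr = struc.AtomArray(topology.n_atoms)
    for i, a in enumerate(topology.atoms):
        arr.atom_name[i] = a.atom_name
        arr.res_name[i] = a.residue_name
        arr.res_id[i] = a.residue_seq
        arr.chain_id[i] = a.chain_id or " "
        arr.element[i] = a.element or a.atom_name[0]
        arr.hetero[i] = a.residue_name in ION_RESIDUE_NAMES
    stack = struc.stack([arr] * trajectory.n_frames)
    stack.coord = trajectory.coords / ANGSTROM_TO_NM

    pdb_file = pdb.PDBFile()
    pdb.set_structure(pdb_file, stack)
    times = " ".join(f"{t:g}" for t in trajectory.frame_times)
    pdb_file.lines.insert(0, f"{_TIME_REMARK_PREFIX} {times}")
    pdb_file.write(str(path))


def write_frames_table(
    path: str | Path, topology: Topology, trajectory: Trajectory
) -> None:
    """Write the TSV frames dialect: frame, time_ns, serial, x, y, z (nm)."""
    rows = []
    serials = [a.serial for a in topology.atoms]
    for fi in range(trajectory.n_frames):
        t = trajectory.frame_times[fi]
        for ai, serial in enumerate(serials):
            x, y, z = trajectory.coords[fi, ai]
            rows.append((fi, t, serial, x, y, z))
    df = pd.DataFrame(rows, columns=["frame", "time_ns", "serial", "x", "y", "z"])
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# mutation tables and report writing
# ---------------------------------------------------------------------------


def read_mutation_table(path: str | Path) -> list[MutationEffect]:
    """Read a TSV of ΔT_d values with columns chain, resseq, resname, delta_td."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["chain", "resseq", "resname", "delta_td"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"mutation table missing columns: {missing}")

    records: list[MutationEffect] = []
    seen: set[tuple[str, int, str]] = set()
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            delta = float(row.delta_td)
        except (TypeError, ValueError) as exc:
            raise SchemaError(
                f"non-numeric delta_td {row.delta_td!r} at row {row_no}"
            ) from exc
        rec = MutationEffect(
            chain_id=str(row.chain),
            residue_seq=int(row.resseq),
            residue_name=str(row.resname),
            delta_td=delta,
        )
        if rec.site in seen:
            raise SchemaError(f"duplicate mutation site {rec.site}")
        seen.add(rec.site)
        records.append(rec)
    return records


#: column-name fragments that select the rendering precision in reports
_PERCENT_HINTS = ("occupancy", "pct", "percent", "sum", "average")
_DISTANCE_HINTS = ("distance", "nm", "rmsd", "rmsf", "rg", "sd")


def write_report(
    table: pd.DataFrame,
    path: str | Path,
    percent_columns: Sequence[str] | None = None,
    distance_columns: Sequence[str] | None = None,
) -> None:
    """Write a report table as UTF-8 TSV.

    Occupancy/percentage columns are rendered with 1 decimal place and
    distance-like columns with 2, matching the precision of the tables the
    pipeline reproduces.  Columns not matched by name keep full precision.
    """
    if table.shape[1] == 0:
        raise ValueError("report table must have at least one column")
    out = table.copy()

    def _is_percent(col: str) -> bool:
        if percent_columns is not None:
            return col in percent_columns
        return any(h in col.lower() for h in _PERCENT_HINTS)

    def _is_distance(col: str) -> bool:
        if distance_columns is not None:
            return col in distance_columns
        return any(h in col.lower() for h in _DISTANCE_HINTS)

    for col in out.columns:
        if not pd.api.types.is_float_dtype(out[col]):
            continue
        if _is_percent(col):
            out[col] = out[col].map(lambda v: f"{v:.1f}" if pd.notna(v) else "")
        elif _is_distance(col):
            out[col] = out[col].map(lambda v: f"{v:.2f}" if pd.notna(v) else "")
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")
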