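"""Structural time-series metrics: superposition RMSD, Rg and per-atom RMSF.

RMSD uses the Kabsch least-squares superposition (SVD with a determinant
correction so the rotation is always proper).  RMSF is computed about the
window-mean structure after one alignment pass, and is reported together
with its difference profile (per-atom RMSF minus the selection mean), which
sums to zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import Topology, Trajectory

#: standard atomic masses (u) for the elements that occur in these topologies
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "CL": 35.45,
    "NA": 22.990,
}


@dataclass
class StructuralSummary:
    """Per-frame RMSD/Rg series and per-atom RMSF with window summaries."""

    rmsd_series: np.ndarray  # nm, per frame in window
    rg_series: np.ndarray  # nm, per frame in window
    rmsf_per_atom: np.ndarray  # nm, per selected atom
    window: tuple[float, float]
    times: np.ndarray

    @property
    def rmsd_mean(self) -> float:
        return float(np.mean(self.rmsd_series))

    @property
    def rmsd_sd(self) -> float:
        return float(np.std(self.rmsd_series, ddof=1))

    @property
    def rg_mean(self) -> float:
        return float(np.mean(self.rg_series))

    @property
    def rg_sd(self) -> float:
        return float(np.std(self.rg_series, ddof=1))

    @property
    def rmsf_mean(self) -> float:
        return float(np.mean(self.rmsf_per_atom))

    @property
    def rmsf_sd(self) -> float:
        return float(np.std(self.rmsf_per_atom, ddof=1))

    def summary_row(self) -> dict[str, str]:
        """Table-style 'mean ± SD' strings at 2 decimals."""
        return {
            "RMSD (nm)": f"{self.rmsd_mean:.2f} ± {self.rmsd_sd:.2f}",
            "Rg (nm)": f"{self.rg_mean:.2f} ± {self.rg_sd:.2f}",
            "RMSF (nm)": f"{self.rmsf_mean:.2f} ± {self.rmsf_sd:.2f}",
        }


def kabsch_align(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper-rotation superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` minimizing
    √(Σ wᵢ‖R·xᵢ + t − yᵢ‖² / Σ wᵢ).  The rotation always has determinant +1
    (reflections are rejected by flipping the smallest singular direction).
    """
    x = np.asarray(mobile, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("point sets must both be (N, 3)")
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a unique superposition")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    wsum = w.sum()

    xc = (w[:, None] * x).sum(axis=0) / wsum
    yc = (w[:, None] * y).sum(axis=0) / wsum
    x0 = x - xc
    y0 = y - yc

    h = (w[:, None] * x0).T @ y0
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = yc - rotation @ xc

    aligned = x @ rotation.T + translation
    rmsd = float(np.sqrt((w * np.sum((aligned - y) ** 2, axis=1)).sum() / wsum))
    return rotation, translation, rmsd


def _selection_indices(topology: Topology, selection: str | None) -> np.ndarray:
    if selection is None:
        idx = np.arange(topology.n_atoms)
    else:
        idx = np.array(
            [i for i, a in enumerate(topology.atoms) if a.atom_name == selection],
            dtype=int,
        )
    if idx.size == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    return idx


def rmsd_series(
    trajectory: Trajectory,
    topology: Topology,
    reference_frame: int = 0,
    selection: str | None = "CA",
    window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame Kabsch RMSD of the selection vs a reference frame.

    Returns ``(times, rmsd)`` for the frames in ``window`` (default: all).
    """
    idx = _selection_indices(topology, selection)
    ref = trajectory.coords[reference_frame][idx]
    mask = (
        np.ones(trajectory.n_frames, dtype=bool)
        if window is None
        else trajectory.window_mask(*window)
    )
    frames = np.nonzero(mask)[0]
    out = np.empty(frames.size)
    for k, fi in enumerate(frames):
        _, _, out[k] = kabsch_align(trajectory.coords[fi][idx], ref)
    return trajectory.frame_times[mask], out


def radius_of_gyration(
    coords: np.ndarray, masses: np.ndarray | None = None
) -> float:
    """Mass-weighted radius of gyration √(Σ mᵢ‖rᵢ−r_cm‖²/Σ mᵢ) in nm."""
    r = np.asarray(coords, dtype=float)
    if r.ndim != 2 or r.shape[1] != 3 or r.shape[0] < 1:
        raise ValueError("coords must be (N, 3) with N ≥ 1")
    if masses is None:
        m = np.ones(r.shape[0])
    else:
        m = np.asarray(masses, dtype=float)
        if m.shape != (r.shape[0],):
            raise ValueError("masses length must equal atom count")
    total = m.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    cm = (m[:, None] * r).sum(axis=0) / total
    return float(np.sqrt((m * np.sum((r - cm) ** 2, axis=1)).sum() / total))


def masses_for(topology: Topology, indices: np.ndarray) -> np.ndarray:
    """Element masses for the given atom indices; unity where unknown."""
    out = np.ones(indices.size)
    for k, i in enumerate(indices):
        el = topology.atoms[i].element.upper()
        out[k] = ATOMIC_MASSES.get(el, 1.0)
    return out


def rg_series(
    trajectory: Trajectory,
    topology: Topology,
    selection: str | None = None,
    window: tuple[float, float] | None = None,
    mass_weighted: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame radius of gyration of the selection."""
    idx = _selection_indices(topology, selection)
    have_elements = any(topology.atoms[i].element for i in idx)
    masses = masses_for(topology, idx) if (mass_weighted and have_elements) else None
    mask = (
        np.ones(trajectory.n_frames, dtype=bool)
        if window is None
        else trajectory.window_mask(*window)
    )
    frames = np.nonzero(mask)[0]
    out = np.empty(frames.size)
    for k, fi in enumerate(frames):
        out[k] = radius_of_gyration(trajectory.coords[fi][idx], masses)
    return trajectory.frame_times[mask], out


def rmsf_per_atom(
    trajectory: Trajectory,
    topology: Topology,
    selection: str | None = "CA",
    window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom RMSF about the window-mean structure, plus difference profile.

    Frames are least-squares aligned to the running mean structure (one
    refinement pass: align to frame 0, form the mean, re-align to the mean,
    recompute the mean).  Returns ``(rmsf, difference_profile)`` where the
    difference profile is per-atom RMSF minus the selection mean and sums to
    zero.
    """
    idx = _selection_indices(topology, selection)
    mask = (
        np.ones(trajectory.n_frames, dtype=bool)
        if window is None
        else trajectory.window_mask(*window)
    )
    frames = np.nonzero(mask)[0]
    if frames.size < 2:
        raise ValueError("RMSF needs at least 2 frames")

    coords = trajectory.coords[frames][:, idx, :].copy()

    def _align_all(target: np.ndarray) -> np.ndarray:
        out = np.empty_like(coords)
        for k in range(coords.shape[0]):
            rot, trans, _ = kabsch_align(coords[k], target)
            out[k] = coords[k] @ rot.T + trans
        return out

    aligned = _align_all(coords[0])
    mean = aligned.mean(axis=0)
    aligned = _align_all(mean)
    mean = aligned.mean(axis=0)

    rmsf = np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))
    diff = rmsf - rmsf.mean()
    return rmsf, diff


def structural_summary(
    trajectory: Trajectory,
    topology: Topology,
    selection: str | None = "CA",
    window: tuple[float, float] | None = None,
    reference_frame: int = 0,
) -> StructuralSummary:
    """RMSD/Rg/RMSF series and summaries over one analysis window."""
    times, rmsd = rmsd_series(
        trajectory, topology, reference_frame, selection, window
    )
    _, rg = rg_series(trajectory, topology, selection=None, window=window)
    rmsf, _ = rmsf_per_atom(trajectory, topology, selection, window)
    win = (
        (float(times[0]), float(times[-1])) if window is None else tuple(window)
    )
    return StructuralSummary(
        rmsd_series=rmsd,
        rg_series=rg,
        rmsf_per_atom=rmsf,
        window=win,
        times=times,
    )
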