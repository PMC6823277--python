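"""Salt-bridge occupancy statistics and their aggregations.

Occupancy of a candidate pair is the percentage of analysis frames in which
the reference-atom distance is strictly below the cutoff (default 0.6 nm).
On top of the per-pair records sit the aggregations the analysis reports:

* per-positive-site sums of partner occupancies, per scope and combined;
* per-site averages over the positive sites of a condition;
* cross-condition grand means (mean ± sample SD over force fields);
* threshold counts (how many targeted pairs exceed 0.1/1/10/... %);
* windowed occupancies over contiguous 100-ns blocks (robustness check);
* counter-ion occupancies (per-ion, summed, and max-single).

Aggregation functions operate on tidy DataFrames with columns
``positive_site, partner, scope, occupancy_pct`` (plus ``condition`` where
relevant) so that they apply equally to pipeline output and to published
occupancy tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import Topology, Trajectory
from .sites import CandidatePair, ChargedSite, DEFAULT_CUTOFF_NM

DEFAULT_THRESHOLDS = (0.1, 1.0, 10.0, 40.0, 70.0, 80.0, 90.0)


@dataclass
class DistanceSeries:
    """Per-frame reference-atom distance of one candidate pair."""

    pair: CandidatePair
    times: np.ndarray  # ns
    distances: np.ndarray  # nm

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.times.shape != self.distances.shape:
            raise ValueError("times and distances must have equal length")
        if np.any(self.distances < 0):
            raise ValueError("distances must be ≥ 0")


@dataclass
class OccupancyRecord:
    """Occupancy and distance statistics of one pair over an analysis window."""

    pair: CandidatePair
    occupancy_pct: float
    mean_distance: float
    sd_distance: float
    n_frames: int


@dataclass
class IonOccupancy:
    """Contact statistics of one charged site with all ions of a species."""

    site: ChargedSite
    species: str
    per_ion: list[tuple[int, float]]  # (atom index of ion, occupancy %)

    @property
    def summed_pct(self) -> float:
        return float(sum(v for _, v in self.per_ion))

    @property
    def max_single_pct(self) -> float:
        return max((v for _, v in self.per_ion), default=0.0)


def distance_series(
    trajectory: Trajectory,
    pair: CandidatePair,
    window: tuple[float, float] | None = None,
) -> DistanceSeries:
    """Euclidean reference-atom distance per frame, optionally windowed."""
    if window is None:
        mask = np.ones(trajectory.n_frames, dtype=bool)
    else:
        mask = trajectory.window_mask(*window)
    diff = (
        trajectory.coords[mask, pair.positive.reference_atom, :]
        - trajectory.coords[mask, pair.negative.reference_atom, :]
    )
    return DistanceSeries(
        pair=pair,
        times=trajectory.frame_times[mask],
        distances=np.linalg.norm(diff, axis=1),
    )


def occupancy_percent(
    series: DistanceSeries, cutoff: float = DEFAULT_CUTOFF_NM
) -> OccupancyRecord:
    """Occupancy = 100 × (frames with d < cutoff)/n, with distance mean ± SD.

    The inequality is strict, so a pair sitting exactly at the cutoff never
    counts as bound.  The SD uses the n−1 denominator.
    """
    d = series.distances
    if d.size == 0:
        raise ValueError("distance series is empty")
    n_below = int(np.sum(d < cutoff))
    return OccupancyRecord(
        pair=series.pair,
        occupancy_pct=100.0 * n_below / d.size,
        mean_distance=float(np.mean(d)),
        sd_distance=float(np.std(d, ddof=1)) if d.size > 1 else 0.0,
        n_frames=int(d.size),
    )


def records_to_frame(
    records: Iterable[OccupancyRecord], condition: str | None = None
) -> pd.DataFrame:
    """Tidy DataFrame view of occupancy records for the aggregation layer."""
    rows = []
    for rec in records:
        rows.append(
            {
                "positive_site": rec.pair.positive.label,
                "partner": rec.pair.negative.label,
                "scope": rec.pair.scope,
                "occupancy_pct": rec.occupancy_pct,
                "mean_distance": rec.mean_distance,
                "sd_distance": rec.sd_distance,
                "n_frames": rec.n_frames,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "positive_site",
            "partner",
            "scope",
            "occupancy_pct",
            "mean_distance",
            "sd_distance",
            "n_frames",
        ],
    )
    if condition is not None:
        df.insert(0, "condition", condition)
    return df


def subunit_average(records: Sequence[OccupancyRecord]) -> OccupancyRecord:
    """Average the same residue pair over the (three) subunits.

    All records must refer to the same (positive resseq, negative resseq)
    residue pair; the returned record keeps the identity of the first and
    carries the arithmetic mean of occupancy and distance statistics.
    """
    if not records:
        raise ValueError("need at least one subunit record")
    key = (
        records[0].pair.positive.residue_seq,
        records[0].pair.positive.kind,
        records[0].pair.negative.residue_seq,
        records[0].pair.negative.kind,
    )
    for rec in records[1:]:
        other = (
            rec.pair.positive.residue_seq,
            rec.pair.positive.kind,
            rec.pair.negative.residue_seq,
            rec.pair.negative.kind,
        )
        if other != key:
            raise ValueError(f"mismatched pair identities: {key} vs {other}")
    return OccupancyRecord(
        pair=records[0].pair,
        occupancy_pct=float(np.mean([r.occupancy_pct for r in records])),
        mean_distance=float(np.mean([r.mean_distance for r in records])),
        sd_distance=float(np.mean([r.sd_distance for r in records])),
        n_frames=int(np.mean([r.n_frames for r in records])),
    )


def aggregate_by_positive_site(table: pd.DataFrame) -> pd.DataFrame:
    """Per-positive-site sums of partner occupancies, per scope and combined.

    Returns one row per positive site with columns ``intra_sum``,
    ``inter_sum`` and ``combined_sum`` (= intra + inter exactly).  Sites
    absent from a scope contribute 0 for that scope.
    """
    required = {"positive_site", "scope", "occupancy_pct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table missing columns: {sorted(missing)}")
    sums = (
        table.groupby(["positive_site", "scope"], sort=False)["occupancy_pct"]
        .sum()
        .unstack("scope", fill_value=0.0)
    )
    for scope in ("intra", "inter"):
        if scope not in sums.columns:
            sums[scope] = 0.0
    out = pd.DataFrame(
        {
            "intra_sum": sums["intra"],
            "inter_sum": sums["inter"],
        }
    )
    out["combined_sum"] = out["intra_sum"] + out["inter_sum"]
    return out.reset_index()


def per_site_average(
    table: pd.DataFrame,
    scope: str = "intra",
    exclude: Sequence[str] | None = None,
) -> float:
    """Mean per-positive-site occupancy sum for one scope.

    ``scope`` may be ``"intra"``, ``"inter"`` or ``"combined"``.  The
    denominator is the number of positive sites listed in the table for that
    scope (after ``exclude``), matching the convention of per-residue table
    averages.
    """
    sums = aggregate_by_positive_site(table)
    if scope == "combined":
        col = "combined_sum"
        present = sums
    elif scope in ("intra", "inter"):
        col = f"{scope}_sum"
        listed = set(table.loc[table["scope"] == scope, "positive_site"])
        present = sums[sums["positive_site"].isin(listed)]
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if exclude:
        present = present[~present["positive_site"].isin(exclude)]
    if present.empty:
        raise ValueError("no positive sites left after exclusion")
    return float(present[col].mean())


def cross_condition_mean(values: Sequence[float]) -> tuple[float, float]:
    """Grand mean and sample SD (n−1) over per-condition averages."""
    if len(values) < 2:
        raise ValueError("need at least two conditions")
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))


def count_above_thresholds(
    occupancies: Sequence[float],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Counts and percentages of targeted pairs with occupancy > threshold.

    The inequality is strict (a pair at exactly 0.1% does not count for the
    ``> 0.1`` row).  Percentages are relative to the full targeted pair list.
    """
    occ = np.asarray(list(occupancies), dtype=float)
    total = occ.size
    if total == 0:
        raise ValueError("no occupancy records")
    rows = []
    for thr in thresholds:
        n = int(np.sum(occ > thr))
        rows.append({"threshold": thr, "count": n, "percent": 100.0 * n / total})
    return pd.DataFrame(rows)


def windowed_occupancy(
    trajectory: Trajectory,
    pairs: Sequence[CandidatePair],
    window_ns: float = 100.0,
    cutoff: float = DEFAULT_CUTOFF_NM,
) -> pd.DataFrame:
    """Occupancy per contiguous time window, plus the cross-window SD.

    Windows are half-open ``[k·w, (k+1)·w)`` anchored at the first frame
    time, except the last window which also includes its right edge.  Frame
    counts per window are reported so that the frame-weighted average of
    window occupancies reconstructs the whole-trajectory occupancy exactly.
    """
    t = trajectory.frame_times
    span = t[-1] - t[0]
    if span < window_ns:
        raise ValueError("trajectory shorter than one window")
    n_windows = int(np.ceil((span - 1e-9) / window_ns))
    edges = t[0] + window_ns * np.arange(n_windows + 1)
    edges[-1] = t[-1]

    rows = []
    for pair in pairs:
        series = distance_series(trajectory, pair)
        bound = series.distances < cutoff
        window_occ = []
        for k in range(n_windows):
            if k < n_windows - 1:
                mask = (t >= edges[k] - 1e-9) & (t < edges[k + 1] - 1e-9)
            else:
                mask = (t >= edges[k] - 1e-9) & (t <= edges[k + 1] + 1e-9)
            n = int(mask.sum())
            occ = 100.0 * bound[mask].sum() / n if n else np.nan
            window_occ.append((occ, n))
            rows.append(
                {
                    "pair": pair.label,
                    "window": k,
                    "start_ns": edges[k],
                    "end_ns": edges[k + 1],
                    "occupancy_pct": occ,
                    "n_frames": n,
                }
            )
        occs = [o for o, n in window_occ if n]
        sd = float(np.std(occs, ddof=1)) if len(occs) > 1 else 0.0
        for row in rows[-n_windows:]:
            row["cross_window_sd"] = sd
    return pd.DataFrame(rows)


def ion_site_occupancy(
    trajectory: Trajectory,
    topology: Topology,
    site: ChargedSite,
    species: str,
    cutoff: float = DEFAULT_CUTOFF_NM,
) -> IonOccupancy:
    """Per-ion occupancy of one charged site with every ion of a species.

    Applies equally to positive residues vs Cl− and negative residues vs
    Na+.  An absent species yields an empty (summed 0) result.
    """
    ion_atoms = [
        i for i in topology.ion_indices if topology.atoms[i].residue_name == species
    ]
    per_ion: list[tuple[int, float]] = []
    ref = trajectory.coords[:, site.reference_atom, :]
    for idx in ion_atoms:
        d = np.linalg.norm(trajectory.coords[:, idx, :] - ref, axis=1)
        per_ion.append((idx, 100.0 * float(np.sum(d < cutoff)) / trajectory.n_frames))
    return IonOccupancy(site=site, species=species, per_ion=per_ion)


def effective_sample_size(binary_series: np.ndarray, max_lag: int | None = None) -> float:
    """ESS of an autocorrelated 0/1 series: n / (1 + 2 Σ ρ_k).

    The autocorrelation sum is truncated at the first non-positive ρ_k
    (initial positive sequence estimator), which is adequate for the
    geometrically mixing two-state chains used in validation.
    """
    x = np.asarray(binary_series, dtype=float)
    n = x.size
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return float(n)
    if max_lag is None:
        max_lag = min(n - 1, 10_000)
    rho_sum = 0.0
    for k in range(1, max_lag + 1):
        rho = np.dot(x[:-k], x[k:]) / (n * var)
        if rho <= 0:
            break
        rho_sum += rho
    return n / (1 + 2 * rho_sum)
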