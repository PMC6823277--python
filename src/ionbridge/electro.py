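"""Burial-scaled Coulomb electrostatics and the energy-vs-ΔT_d regression.

The scorer assigns unit formal charges to the side-chain reference atoms of
charged sites (+1 for Arg/Lys/N-terminus, −1 for Asp/Glu/C-terminus) and
evaluates Coulomb's law with an effective dielectric that interpolates
linearly between a solvent-exposed value (ε = 80) and a buried value
(ε = 4) according to how deeply the interacting pair is buried.  Burial of a
site is proxied by its heavy-atom neighbor count, saturating at
``burial_saturation_count`` neighbors within ``burial_radius``.

This is deliberately a simple, self-contained scorer with a qualitative
contract — repulsive like-charge clusters score positive (destabilizing),
buried contacts are amplified relative to exposed ones — not a full
empirical force field.  Per-site ensemble energies are averaged over
structural snapshots and regressed against experimental denaturation-
temperature shifts (ΔT_d, °C) by ordinary least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import MutationEffect, Topology, Trajectory
from .sites import ChargedSite

#: Coulomb constant f = 1/(4πε₀) in kJ·mol⁻¹·nm·e⁻²
COULOMB_CONSTANT = 138.935


@dataclass
class ElectroParams:
    """Parameters of the burial-scaled Coulomb scorer (all config keys)."""

    coulomb_constant: float = COULOMB_CONSTANT
    eps_exposed: float = 80.0
    eps_buried: float = 4.0
    burial_radius: float = 0.9  # nm
    burial_saturation_count: int = 30

    def __post_init__(self) -> None:
        if self.eps_buried >= self.eps_exposed:
            raise ValueError("eps_buried must be < eps_exposed")
        if min(
            self.coulomb_constant,
            self.eps_exposed,
            self.eps_buried,
            self.burial_radius,
            self.burial_saturation_count,
        ) <= 0:
            raise ValueError("all electrostatics parameters must be positive")

    def dielectric(self, burial: float) -> float:
        """Linear interpolation ε(b) = ε_exposed + b·(ε_buried − ε_exposed)."""
        return self.eps_exposed + burial * (self.eps_buried - self.eps_exposed)


@dataclass
class ResidueEnergy:
    """Net electrostatic energy at one site (kJ·mol⁻¹, positive = repulsive)."""

    site: ChargedSite
    energy: float
    burial: float
    n_snapshots: int = 1


@dataclass
class RegressionResult:
    """OLS fit of ΔT_d on per-site electrostatic energy.

    ``r`` is the Pearson correlation, ``sd`` the residual standard deviation
    √(SSE/(n−2)) and ``p`` the two-sided t-test p-value on the correlation
    with n−2 degrees of freedom.
    """

    slope: float
    intercept: float
    r: float
    sd: float
    p: float
    n: int

    def summary(self) -> str:
        return (
            f"ΔT_d ~ energy (n = {self.n})\n"
            f"  slope     {self.slope: .4f} °C per kJ·mol⁻¹\n"
            f"  intercept {self.intercept: .4f} °C\n"
            f"  R         {self.r: .3f}\n"
            f"  SD        {self.sd: .1f} °C\n"
            f"  P         {self.p: .3g}"
        )


def site_charge(site: ChargedSite) -> float:
    """Unit formal charge of a site (+1 or −1)."""
    return float(site.polarity)


def burial_fraction(
    site: ChargedSite,
    frame_coords: np.ndarray,
    topology: Topology,
    params: ElectroParams | None = None,
) -> float:
    """Burial proxy: saturating heavy-atom neighbor count in [0, 1].

    Counts heavy (non-hydrogen) atoms outside the site's own residue within
    ``burial_radius`` of the reference atom and divides by the saturation
    count, clipping at 1.
    """
    params = params or ElectroParams()
    ref = frame_coords[site.reference_atom]
    own = set(topology.residue_atom_indices(site.chain_id, site.residue_seq))
    n = 0
    for i, atom in enumerate(topology.atoms):
        if i in own or atom.element.upper() == "H":
            continue
        if np.linalg.norm(frame_coords[i] - ref) < params.burial_radius:
            n += 1
    return min(1.0, n / params.burial_saturation_count)


def pair_coulomb_energy(
    q_i: float,
    q_j: float,
    r: float,
    burial_pair: float,
    params: ElectroParams | None = None,
) -> float:
    """E = f·qᵢ·qⱼ / (ε(b)·r) in kJ·mol⁻¹, with b the mean pair burial."""
    params = params or ElectroParams()
    if r <= 0:
        raise ValueError("distance must be positive")
    return params.coulomb_constant * q_i * q_j / (params.dielectric(burial_pair) * r)


def residue_energy(
    site: ChargedSite,
    frame_coords: np.ndarray,
    charged_sites: list[ChargedSite],
    topology: Topology,
    params: ElectroParams | None = None,
) -> ResidueEnergy:
    """Single-frame net energy of one site against all other charged sites.

    No distance cutoff is applied (the interaction is long-ranged).  Each
    site sums its own pairs, so summing over all sites counts every
    unordered pair twice.
    """
    params = params or ElectroParams()
    if site not in charged_sites:
        raise ValueError("site must be among the charged sites")
    b_self = burial_fraction(site, frame_coords, topology, params)
    q_self = site_charge(site)
    total = 0.0
    for other in charged_sites:
        if other == site:
            continue
        r = float(
            np.linalg.norm(
                frame_coords[site.reference_atom] - frame_coords[other.reference_atom]
            )
        )
        b_other = burial_fraction(other, frame_coords, topology, params)
        total += pair_coulomb_energy(
            q_self, site_charge(other), r, (b_self + b_other) / 2, params
        )
    return ResidueEnergy(site=site, energy=total, burial=b_self, n_snapshots=1)


def ensemble_energy(
    trajectory: Trajectory,
    topology: Topology,
    site: ChargedSite,
    charged_sites: list[ChargedSite],
    snapshot_times_ns: list[float],
    params: ElectroParams | None = None,
) -> ResidueEnergy:
    """Arithmetic mean of per-snapshot residue energies over a schedule."""
    params = params or ElectroParams()
    energies = []
    burials = []
    for t in snapshot_times_ns:
        fi = trajectory.frame_at_time(t)
        res = residue_energy(site, trajectory.coords[fi], charged_sites, topology, params)
        energies.append(res.energy)
        burials.append(res.burial)
    return ResidueEnergy(
        site=site,
        energy=float(np.mean(energies)),
        burial=float(np.mean(burials)),
        n_snapshots=len(snapshot_times_ns),
    )


def regress_energy_vs_dtd(
    energies: dict[tuple[str, int, str], float] | list[ResidueEnergy],
    mutations: list[MutationEffect],
) -> RegressionResult:
    """OLS of ΔT_d on per-site electrostatic energy over matched sites.

    ``energies`` maps (chain, resseq, resname) to kJ·mol⁻¹ (ResidueEnergy
    lists are accepted and converted).  Sites without a matching mutation
    record, and vice versa, are dropped; at least 3 matched points and a
    non-degenerate energy spread are required.
    """
    if not isinstance(energies, dict):
        energies = {
            (e.site.chain_id, e.site.residue_seq, e.site.residue_name): e.energy
            for e in energies
        }
    xs, ys = [], []
    for mut in mutations:
        if mut.site in energies:
            xs.append(energies[mut.site])
            ys.append(mut.delta_td)
    n = len(xs)
    if n < 3:
        raise ValueError(f"need ≥3 matched (energy, ΔT_d) points, got {n}")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in energies")

    fit = stats.linregress(x, y)
    residuals = y - (fit.slope * x + fit.intercept)
    sd = float(np.sqrt(np.sum(residuals**2) / (n - 2))) if n > 2 else 0.0
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        sd=sd,
        p=float(fit.pvalue),
        n=n,
    )
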