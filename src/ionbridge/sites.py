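"""Ionizable-site identification, candidate-pair enumeration and screening.

A salt bridge is operationalized on side-chain reference atoms: the Cε atom
of Lys (CE) or Cζ of Arg (CZ) against the Cγ of Asp (CG) or Cδ of Glu (CD).
Chain termini contribute sites of their own (backbone N of the first residue,
carboxyl C of the last).  His is never treated as positively charged here.

Candidate (+,−) pairs are split by scope — intra-subunit when both sites sit
on the same chain, inter-subunit otherwise — and screened by the snapshot
rule: a pair is retained when its reference-atom distance drops below the
cutoff (default 0.6 nm, strict inequality) in at least one screening
snapshot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import Topology, Trajectory

POSITIVE_SIDECHAINS = {"LYS": "CE", "ARG": "CZ"}
NEGATIVE_SIDECHAINS = {"ASP": "CG", "GLU": "CD"}

DEFAULT_CUTOFF_NM = 0.6


@dataclass(frozen=True)
class ChargedSite:
    """One ionizable site with its reference atom in the topology."""

    chain_id: str
    residue_seq: int
    residue_name: str
    kind: str  # sidechain_pos | sidechain_neg | n_terminus | c_terminus | ion
    reference_atom: int  # atom index into the topology

    @property
    def polarity(self) -> int:
        if self.kind in ("sidechain_pos", "n_terminus"):
            return +1
        if self.kind in ("sidechain_neg", "c_terminus"):
            return -1
        if self.kind == "ion":
            return +1 if self.residue_name == "NA" else -1
        raise ValueError(f"unknown site kind {self.kind!r}")

    @property
    def label(self) -> str:
        if self.kind == "n_terminus":
            return f"{self.chain_id}:N-terminal"
        if self.kind == "c_terminus":
            return f"{self.chain_id}:C-terminal"
        return f"{self.chain_id}:{self.residue_name}{self.residue_seq}"


@dataclass(frozen=True)
class CandidatePair:
    """A favorable (+,−) pairing with intra/inter-subunit scope."""

    positive: ChargedSite
    negative: ChargedSite

    def __post_init__(self) -> None:
        if self.positive.polarity != +1 or self.negative.polarity != -1:
            raise ValueError("pair must combine a +1 site with a −1 site")

    @property
    def scope(self) -> str:
        return "intra" if self.positive.chain_id == self.negative.chain_id else "inter"

    @property
    def label(self) -> str:
        return f"{self.positive.label}--{self.negative.label}"


@dataclass
class ScreeningRule:
    """Snapshot screening: distance < cutoff at least once among the times."""

    times: list[float]
    cutoff: float = DEFAULT_CUTOFF_NM
    criterion: str = "at_least_once"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if not self.times:
            raise ValueError("screening times must be non-empty")
        if self.criterion != "at_least_once":
            raise ValueError(f"unknown screening criterion {self.criterion!r}")


def identify_charged_sites(
    topology: Topology,
    include_termini: bool = True,
    include_ions: bool = False,
    c_terminus_atom: str = "C",
) -> list[ChargedSite]:
    """Enumerate ionizable sites of a topology.

    Arg/Lys side chains are positive (reference atoms CZ/CE), Asp/Glu side
    chains negative (CG/CD).  With ``include_termini`` the first residue of
    each polymer chain contributes an N-terminal positive site (atom N) and
    the last a C-terminal negative site (``c_terminus_atom``, falling back to
    OXT and then to C/OXT alternatives).  With ``include_ions`` each CL/NA
    record becomes an ion site.  Residues whose reference atom is missing are
    skipped with a warning.
    """
    sites: list[ChargedSite] = []
    skipped = 0

    for chain_id, residue_seq, residue_name in topology.residues():
        ref_name = POSITIVE_SIDECHAINS.get(residue_name) or NEGATIVE_SIDECHAINS.get(
            residue_name
        )
        if ref_name is None:
            continue
        idx = topology.atom_index(chain_id, residue_seq, ref_name)
        if idx is None:
            warnings.warn(
                f"residue {residue_name}{residue_seq} chain {chain_id}: reference "
                f"atom {ref_name} missing; site skipped",
                stacklevel=2,
            )
            skipped += 1
            continue
        kind = (
            "sidechain_pos" if residue_name in POSITIVE_SIDECHAINS else "sidechain_neg"
        )
        sites.append(ChargedSite(chain_id, residue_seq, residue_name, kind, idx))

    if include_termini:
        for chain_id in topology.chains():
            chain_res = topology.chain_residues(chain_id)
            if not chain_res:
                continue
            first_seq, first_name = chain_res[0]
            last_seq, last_name = chain_res[-1]
            n_idx = topology.atom_index(chain_id, first_seq, "N")
            if n_idx is not None:
                sites.append(
                    ChargedSite(chain_id, first_seq, first_name, "n_terminus", n_idx)
                )
            else:
                warnings.warn(
                    f"chain {chain_id}: N-terminal backbone N missing", stacklevel=2
                )
                skipped += 1
            c_idx = topology.atom_index(chain_id, last_seq, c_terminus_atom)
            if c_idx is None and c_terminus_atom != "OXT":
                c_idx = topology.atom_index(chain_id, last_seq, "OXT")
            if c_idx is None and c_terminus_atom != "C":
                c_idx = topology.atom_index(chain_id, last_seq, "C")
            if c_idx is not None:
                sites.append(
                    ChargedSite(chain_id, last_seq, last_name, "c_terminus", c_idx)
                )
            else:
                warnings.warn(
                    f"chain {chain_id}: C-terminal carbon missing", stacklevel=2
                )
                skipped += 1

    if include_ions:
        for idx in topology.ion_indices:
            a = topology.atoms[idx]
            sites.append(
                ChargedSite(a.chain_id, a.residue_seq, a.residue_name, "ion", idx)
            )

    if skipped:
        warnings.warn(f"{skipped} site(s) skipped for missing atoms", stacklevel=2)
    return sites


def enumerate_candidate_pairs(sites: list[ChargedSite]) -> list[CandidatePair]:
    """All (+,−) combinations of non-ion sites, deterministically ordered.

    Ordering is by (chain, residue_seq) of the positive site, then of the
    negative site, so reports and screenings are reproducible.  Ion sites are
    excluded: residue–ion contacts are handled by the occupancy module.
    """
    positives = sorted(
        (s for s in sites if s.kind != "ion" and s.polarity == +1),
        key=lambda s: (s.chain_id, s.residue_seq, s.kind),
    )
    negatives = sorted(
        (s for s in sites if s.kind != "ion" and s.polarity == -1),
        key=lambda s: (s.chain_id, s.residue_seq, s.kind),
    )
    return [CandidatePair(p, n) for p in positives for n in negatives]


def snapshot_times(start_ns: float, end_ns: float, step_ns: float) -> list[float]:
    """Arithmetic snapshot schedule, inclusive of both endpoints.

    E.g. (100, 400, 10) yields 31 times and (100, 400, 20) yields 16.
    """
    if step_ns <= 0:
        raise ValueError("step must be positive")
    if end_ns < start_ns:
        raise ValueError("end must be ≥ start")
    n_steps = int(np.floor((end_ns - start_ns) / step_ns + 1e-9))
    return [start_ns + k * step_ns for k in range(n_steps + 1)]


def screen_pairs(
    pairs: list[CandidatePair],
    trajectory: Trajectory,
    rule: ScreeningRule,
) -> list[CandidatePair]:
    """Retain pairs whose reference-atom distance is < cutoff in ≥1 snapshot."""
    frame_indices = [trajectory.frame_at_time(t) for t in rule.times]
    coords = trajectory.coords[frame_indices]  # (S, A, 3)

    retained: list[CandidatePair] = []
    for pair in pairs:
        d = np.linalg.norm(
            coords[:, pair.positive.reference_atom, :]
            - coords[:, pair.negative.reference_atom, :],
            axis=1,
        )
        if np.min(d) < rule.cutoff:
            retained.append(pair)
    return retained
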