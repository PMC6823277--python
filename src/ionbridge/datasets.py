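"""Bundled reference datasets.

Per-pair salt-bridge occupancy tables reported for the PhCutA1 trimer from
400-ns MD simulations under six force-field/water-model combinations, plus
the per-residue counter-ion (Cl−) occupancy table.  These serve as fixed
inputs to the aggregation layer — per-site sums, per-site averages and
cross-condition grand means are recomputed from them, not stored.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: the six force-field/water-model condition labels, in canonical order
CONDITIONS = (
    "Charmm27_tip3p",
    "Amber99sb_spce",
    "Amber99sb_tip3p",
    "Amber14sb_tip3p",
    "Gromos43a1_spce",
    "Gromos53a6_spce",
)


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("ionbridge.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_occupancy_table(scope: str = "both") -> pd.DataFrame:
    """Tidy per-pair occupancy table.

    Columns: ``condition, positive_site, partner, scope, occupancy_pct``.
    ``scope`` selects ``"intra"``, ``"inter"`` or ``"both"``.
    """
    frames = []
    wanted = ("intra", "inter") if scope == "both" else (scope,)
    for sc in wanted:
        if sc not in ("intra", "inter"):
            raise ValueError(f"unknown scope {sc!r}")
        wide = _read(f"phcuta1_{sc}_occupancy.tsv")
        long = wide.melt(
            id_vars=["positive_site", "partner"],
            value_vars=list(CONDITIONS),
            var_name="condition",
            value_name="occupancy_pct",
        )
        long["scope"] = sc
        frames.append(long)
    df = pd.concat(frames, ignore_index=True)
    return df[["condition", "positive_site", "partner", "scope", "occupancy_pct"]]


def load_ion_occupancy_table() -> pd.DataFrame:
    """Per-positive-residue combined occupancies with residues and with Cl−.

    Columns: ``positive_site, condition, residue_occupancy_pct,
    chloride_occupancy_pct``.
    """
    return _read("phcuta1_ion_occupancy.tsv")
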