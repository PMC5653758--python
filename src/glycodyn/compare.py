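"""Side-by-side comparison of a nonfucosylated and a fucosylated run.

Produces the per-glycan RMSF table (one row per glycan site, both systems
plus the difference) and paired distance-distribution overlays between the
Fc chain-A GlcNAc1 and the inner residues of the receptor Asn162 glycan.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .analysis import compute_rmsf, aggregate_rmsf, distance_distribution
from .errors import AnalysisError
from .system import Trajectory
from .toy import glycan_groups

__all__ = ["compare_systems", "paired_distance_overlays", "INNER_RESIDUES"]

#: Inner residues of the receptor Asn162 glycan probed against Fc GlcNAc1.
INNER_RESIDUES = ("GlcNAc1", "GlcNAc2", "Man3", "Man4")


def _site_groups(traj: Trajectory) -> dict[str, list[int]]:
    groups = glycan_groups(traj.labels)
    if not groups:
        raise AnalysisError("no glycan-labeled beads found in trajectory")
    return groups


def compare_systems(
    traj_a: Trajectory,
    traj_b: Trajectory,
    name_a: str = "nonfucosylated",
    name_b: str = "fucosylated",
) -> pd.DataFrame:
    """Per-glycan RMSF table for two systems with a difference column.

    Both trajectories must expose the same glycan site groups; a mismatch
    (a site present in one run only) is an error, not a silent drop.
    """
    ga = _site_groups(traj_a)
    gb = _site_groups(traj_b)
    if set(ga) != set(gb):
        only_a = sorted(set(ga) - set(gb))
        only_b = sorted(set(gb) - set(ga))
        raise AnalysisError(
            f"glycan groupings differ: only in {name_a}: {only_a}; "
            f"only in {name_b}: {only_b}"
        )
    prof_a = compute_rmsf(traj_a)
    prof_b = compute_rmsf(traj_b)
    agg_a = aggregate_rmsf(prof_a, ga)
    agg_b = aggregate_rmsf(prof_b, gb)
    rows = []
    for site in sorted(ga):
        rows.append(
            {
                "glycan": site,
                f"rmsf_{name_a}_A": agg_a[site],
                f"rmsf_{name_b}_A": agg_b[site],
                "difference_A": agg_b[site] - agg_a[site],
            }
        )
    return pd.DataFrame(rows)


def paired_distance_overlays(
    traj_a: Trajectory,
    traj_b: Trajectory,
    bins: int = 40,
) -> pd.DataFrame:
    """Distance distributions Fc-A GlcNAc1 ↔ inner Asn162 residues, both runs.

    Histograms share bin edges across the two systems so the overlays are
    directly comparable; returns a long-format table.
    """
    rows = []
    for inner in INNER_RESIDUES:
        try:
            idx_fc_a = [traj_a.labels.index("Fc-A/GlcNAc1")]
            idx_in_a = [traj_a.labels.index(f"Asn162/{inner}")]
            idx_fc_b = [traj_b.labels.index("Fc-A/GlcNAc1")]
            idx_in_b = [traj_b.labels.index(f"Asn162/{inner}")]
        except ValueError as exc:
            raise AnalysisError(f"bead missing for distance pair: {exc}") from exc
        da = distance_distribution(traj_a, idx_fc_a, idx_in_a, bins=bins)
        hi = float(
            max(
                da.distances.max(),
                distance_distribution(traj_b, idx_fc_b, idx_in_b, bins=bins).distances.max(),
            )
        )
        edges = np.linspace(0.0, hi * 1.05, bins + 1)
        da = distance_distribution(traj_a, idx_fc_a, idx_in_a, edges=edges)
        db = distance_distribution(traj_b, idx_fc_b, idx_in_b, edges=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        for c, va, vb in zip(centers, da.density, db.density):
            rows.append(
                {
                    "pair": f"Fc-A/GlcNAc1 vs Asn162/{inner}",
                    "distance_A": c,
                    "density_nonfucosylated": va,
                    "density_fucosylated": vb,
                }
            )
    return pd.DataFrame(rows)
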