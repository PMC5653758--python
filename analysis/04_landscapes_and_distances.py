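"""Free-energy landscapes of the receptor Asn162 glycan and inter-glycan
distance distributions.

For each glycoform: mass-weighted PCA of the Asn162 glycan beads in the
300 K production ensemble, the DG(phi1, phi2) landscape at 300 K, and the
location of the build (crystal-like) conformation on that landscape. Also
the distance distributions between Fc chain-A GlcNAc1 and the inner Asn162
residues. Writes results/fel_<system>.tsv, results/fel_reference_bins.json
and results/distance_overlays.tsv.
"""

import json
from pathlib import Path

import numpy as np

from glycodyn.analysis import free_energy_landscape, landscape_locate, pca
from glycodyn.compare import paired_distance_overlays
from glycodyn.system import Trajectory
from glycodyn.toy import ToyComplexSpec, build_toy_complex

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"
BURN_IN = 0.5

trajs = {}
locate = {}
for name, fuc in (("nonfucosylated", False), ("fucosylated", True)):
    path = SCRATCH / f"{name}_T300.0K.npz"
    if not path.exists():
        raise SystemExit(f"{path} missing; run 02_run_remd.py first")
    traj = Trajectory.load(path).discard_burn_in(BURN_IN)
    trajs[name] = traj
    sel = [i for i, lab in enumerate(traj.labels) if lab.startswith("Asn162/")]
    result = pca(traj, selection=sel, mass_weighted=True, n_components=5)
    fel = free_energy_landscape(result.projections[:, 0], result.projections[:, 1],
                                temperature=300.0, bins=30)
    (RESULTS / f"fel_{name}.tsv").write_text(fel.to_tsv())
    # project the build conformation (the crystal-like reference) onto the PCs
    toy = build_toy_complex(ToyComplexSpec(fc_fucosylated=fuc))
    ref = toy.system.positions[sel]
    w = np.sqrt(traj.masses[sel])[:, None]
    ref_proj = ((ref - result.mean_coords) * w).ravel() @ result.eigenvectors[:, :2]
    locate[name] = landscape_locate(fel, (ref_proj[0], ref_proj[1]))
    pc1_share = result.eigenvalues[0] / result.eigenvalues.sum()
    print(f"{name}: PC1 carries {100 * pc1_share:.0f}% of the Asn162 glycan "
          f"fluctuation; crystal-like reference bin: {locate[name]}")

(RESULTS / "fel_reference_bins.json").write_text(json.dumps(locate, indent=2) + "\n")
overlays = paired_distance_overlays(trajs["nonfucosylated"], trajs["fucosylated"])
overlays.to_csv(RESULTS / "distance_overlays.tsv", sep="\t", index=False,
                float_format="%.6f")
print("Distance overlays (Fc-A GlcNAc1 vs inner Asn162 residues) written to "
      "results/distance_overlays.tsv")
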