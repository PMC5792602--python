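"""Strand-pair rupture order and ligand-pair separations along a pull.

Tracks the geometric-centre (GC) separation of adjacent strand pairs
during a bare pull of the barrel fixture, orders the pairs by the
extension at which they separate, and compares the Gly45-Met121
ligand-pair distance between bare and copper-constrained pulls — the
plateau difference is the chain length sequestered by the coordination
sphere.

Writes results/gc_rupture_order.csv and results/ligand_pair_series.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from azmech.contour import metal_sequestration_shift
from azmech.pulling import PullingProtocol, build_model, run_pull
from azmech.synthetic import generate_toy_barrel
from azmech.trajectory import gc_distance_change, pairs_from_model, residue_pair_distance, rupture_order

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    barrel = generate_toy_barrel(8, 6, with_metal_site=True, seed=0)
    apo = build_model(barrel, metal_mode="none")
    holo = build_model(barrel, metal_mode="full", metal_k=25.0)
    proto = PullingProtocol(velocity=0.05, max_extension=10.0, stride=500, seed=100)

    traj_apo, _ = run_pull(apo, proto)
    pair_names = [("b7", "b8"), ("b6", "b7"), ("b5", "b6"), ("b4", "b5"), ("b1", "b2")]
    pairs = pairs_from_model(barrel, pair_names)
    series = gc_distance_change(traj_apo.residue_frames, traj_apo.extensions, pairs)
    ruptured, intact = rupture_order(series, threshold=0.5)
    print("strand-pair rupture order (bare pull from the C-terminal strand):")
    for name, ext in ruptured:
        print(f"  {name}: ruptured at {ext:.2f} nm")
    if intact:
        print(f"  intact within {proto.max_extension} nm: {', '.join(intact)}")
    pd.DataFrame(
        [{"pair": n, "rupture_extension_nm": e} for n, e in ruptured]
        + [{"pair": n, "rupture_extension_nm": np.nan} for n in intact]
    ).to_csv(RESULTS / "gc_rupture_order.csv", index=False)

    # Gly45-Met121 analogue separation, bare vs constrained
    lig = {b.label.split(":")[0]: b.residue_index for b in barrel.metal.bonds}
    pair = {"Gly45-Met121": (lig["Gly45"], lig["Met121"])}
    traj_holo, _ = run_pull(holo, proto)
    apo_series = residue_pair_distance(traj_apo.residue_frames, pair)["Gly45-Met121"]
    holo_series = residue_pair_distance(traj_holo.residue_frames, pair)["Gly45-Met121"]
    n = min(apo_series.size, holo_series.size)
    shift = metal_sequestration_shift(apo_series[:n], holo_series[:n])
    print(f"Gly45-Met121 separation plateau: bare exceeds constrained by {shift:.2f} nm")
    pd.DataFrame({
        "extension_nm": traj_apo.extensions[:n],
        "apo_gly45_met121_nm": apo_series[:n],
        "holo_gly45_met121_nm": holo_series[:n],
    }).to_csv(RESULTS / "ligand_pair_series.csv", index=False)
    print(f"wrote gc_rupture_order.csv and ligand_pair_series.csv under {RESULTS}")


if __name__ == "__main__":
    main()
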