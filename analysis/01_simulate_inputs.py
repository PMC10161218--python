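"""Generate every synthetic input the downstream drivers consume.

Writes T-jump trace sets for the four environments (buffer, cytosol,
nucleus, nuclear speckles), FRAP traces for the six RNA constructs,
two-channel focus fields, and native/unwound toy ATP-binding trajectories.
Raw traces/images/PDBs go to scratch/synthetic/ (regenerable); the planted
ground truth goes alongside as JSON.
"""

import json
from pathlib import Path

import numpy as np

from cagrna import io
from cagrna.thermo import MeltingParameters
from cagrna.tjump import JumpProtocol
from cagrna.synthetic import (NoiseSpec, gen_atp_binding_trajectory,
                              gen_cag_hairpin, gen_foci_images, gen_frap_trace,
                              gen_partition_image, gen_tjump_experiment)
from cagrna.contacts import write_trajectory

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "synthetic"

# study conditions: dG37 (kJ/mol) per environment with T_m fixed by the
# buffer fit; g1 follows from dG37 = (310 - T_m) * g1
ENVIRONMENTS = {"dpbs": 20.7, "cytosol": 6.8, "nucleus": 6.0, "speckles": 6.4}
TM_BUFFER = 349.0

# mobile fractions per construct (group means reported per cell below)
FRAP_GROUPS = {"cag20": 0.46, "htt_cag17": 0.25, "htt_cag49": 0.28,
               "htt_cag72": 0.23, "scrambled": 0.79, "randomized_50gc": 0.89}

PROTOCOL = JumpProtocol(target_temperatures=tuple(np.linspace(303.0, 358.0, 19)),
                        start_temperature=300.0)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    for name, dg37 in ENVIRONMENTS.items():
        params = MeltingParameters(tm=TM_BUFFER, g1=-dg37 / (TM_BUFFER - 310.0))
        exp = gen_tjump_experiment(params, PROTOCOL, NoiseSpec(0.005, 100))
        d = OUT / "tjump" / name
        d.mkdir(parents=True, exist_ok=True)
        for k, trace in enumerate(exp.traces):
            io.write_trace_csv(trace, d / f"jump_{k:02d}.csv")
        io.write_protocol_yaml(PROTOCOL, d / "protocol.yaml")
        io.write_json({"tm": params.tm, "g1": params.g1, "dg37": dg37},
                      d / "truth.json")
        print(f"tjump/{name}: 19 traces, planted dG37 = {dg37} kJ/mol")

    frap_dir = OUT / "frap"
    frap_dir.mkdir(exist_ok=True)
    for name, fm in FRAP_GROUPS.items():
        for cell in range(8):
            trace, truth = gen_frap_trace(fm, 8.0, 0.8,
                                          NoiseSpec(0.01, 1000 + 17 * cell))
            io.write_frap_csv(trace, frap_dir / f"{name}_cell{cell}.csv")
        io.write_json({"f_mobile": fm}, frap_dir / f"{name}_truth.json")
        print(f"frap/{name}: 8 cells, planted f_mobile = {fm}")

    import tifffile
    foci_dir = OUT / "foci"
    foci_dir.mkdir(exist_ok=True)
    for fov in range(5):
        field = gen_foci_images(overlap_area_fraction=0.45,
                                noise=NoiseSpec(0.01, 2000 + fov))
        tifffile.imwrite(foci_dir / f"fov{fov}_rna.tif",
                         field.rna.pixels.astype(np.float32))
        tifffile.imwrite(foci_dir / f"fov{fov}_speckle.tif",
                         field.speckle.pixels.astype(np.float32))
        io.write_json({"true_overlap_fraction": field.true_overlap_fraction},
                      foci_dir / f"fov{fov}_truth.json")
    img, speckle, nucleus, truth = gen_partition_image(2.5, NoiseSpec(0.0, 2100))
    tifffile.imwrite(foci_dir / "pc_rna.tif", img.pixels.astype(np.float32))
    tifffile.imwrite(foci_dir / "pc_speckle_mask.tif",
                     speckle.astype(np.uint8))
    tifffile.imwrite(foci_dir / "pc_nucleus_mask.tif", nucleus.astype(np.uint8))
    io.write_json(truth, foci_dir / "pc_truth.json")
    print("foci: 5 fields planted at 45% overlap + one PC=2.5 image")

    md_dir = OUT / "md"
    md_dir.mkdir(exist_ok=True)
    hairpin = gen_cag_hairpin(20)
    # native state: occasional WC-edge contact; unwound: frequent contact
    native = gen_atp_binding_trajectory(hairpin, 30, "O6", n_frames=20,
                                        bound_fraction=0.2, seed=1)
    unwound = gen_atp_binding_trajectory(hairpin, 30, "O6", n_frames=20,
                                         bound_fraction=0.8, seed=2)
    write_trajectory(native, md_dir / "native.pdb")
    write_trajectory(unwound, md_dir / "unwound.pdb")
    io.write_json({"bound_fraction": {"native": 0.2, "unwound": 0.8},
                   "target": "G30:O6"}, md_dir / "truth.json")
    print("md: native/unwound toy trajectories (20 frames each)")


if __name__ == "__main__":
    main()
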