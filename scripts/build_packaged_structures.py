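"""Regenerate the sixteen packaged structure JSON files.

Each packaged structure is a finite representative instance (backbone
length 20) produced by the corresponding generator at a fixed seed.  The
script asserts that every instance exposes the bond classes its
degradation-activity set is keyed on, so the packaged fixtures stay in sync
with the activity registry, then writes canonical JSON under
src/psdmap/data/structures/.

Run from the repository root:  python scripts/build_packaged_structures.py
"""

from __future__ import annotations

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from psdmap.activities import required_activities  # noqa: E402
from psdmap.digestion import digest  # noqa: E402
from psdmap.generators import default_params, generate_structure  # noqa: E402
from psdmap.structures import PACKAGED_STRUCTURES, save_structure  # noqa: E402

# fixed seeds; chosen so every representative instance carries all of the
# bond classes listed in EXPECTED_ACTIVITIES below
SEEDS = {name: 20120716 for name in PACKAGED_STRUCTURES}
SEEDS["xyloglucan_xxxg"] = 20120717

EXPECTED_ACTIVITIES = {
    "starch": {"α-amylase", "glucoamylase", "α-glucosidase"},
    "cellulose": {"endo-1,4-β-glucanase", "β-glucosidase"},
    "pullulan": {"α-amylase", "pullulanase", "glucoamylase", "α-glucosidase"},
    "inulin": {"endo-inulinase", "exo-inulinase"},
    "galactomannan": {"endo-1,4-β-D-mannanase", "β-mannosidase",
                      "α-galactosidase"},
    "insoluble_galactoglucomannan": {
        "endo-1,4-β-D-mannanase", "β-mannosidase", "β-glucosidase",
        "α-galactosidase", "acetyl esterase"},
    "soluble_galactoglucomannan": {
        "endo-1,4-β-D-mannanase", "β-mannosidase", "β-glucosidase",
        "α-galactosidase", "β-galactosidase", "acetyl esterase"},
    "smooth_pectin": {"endo-polygalacturonase", "exo-polygalacturonase",
                      "pectin methyl esterase"},
    "xylogalacturonan": {"endo-polygalacturonase", "exo-polygalacturonase",
                         "β-xylosidase", "pectin methyl esterase"},
    "xylan": {"endo-1,4-β-xylanase", "β-xylosidase",
              "arabinoxylan arabinofuranohydrolase", "α-glucuronidase",
              "acetyl xylan esterase"},
    "xyloglucan_xxgg": {"endo-1,4-β-glucanase", "β-glucosidase",
                        "α-xylosidase"},
    "xyloglucan_xxxg": {"endo-1,4-β-glucanase", "β-glucosidase",
                        "α-xylosidase", "β-galactosidase", "α-fucosidase"},
    "arabinogalactan_i": {"endo-1,4-β-galactanase", "β-galactosidase",
                          "α-arabinofuranosidase"},
    "arabinogalactan_ii": {"endo-1,3-β-galactanase", "β-galactosidase",
                           "α-arabinofuranosidase", "β-glucuronidase"},
    "arabinan": {"endo-1,5-α-arabinanase", "α-arabinofuranosidase",
                 "endo-polygalacturonase", "exo-polygalacturonase",
                 "endo-rhamnogalacturonase", "α-rhamnosidase",
                 "β-galactosidase", "feruloyl esterase"},
    "rhamnogalacturonan_i": {"endo-rhamnogalacturonase", "α-rhamnosidase",
                             "exo-polygalacturonase", "β-galactosidase",
                             "α-arabinofuranosidase",
                             "rhamnogalacturonan acetyl esterase"},
}


def main() -> None:
    outdir = ROOT / "src" / "psdmap" / "data" / "structures"
    outdir.mkdir(parents=True, exist_ok=True)
    for name in PACKAGED_STRUCTURES:
        seed = SEEDS[name]
        structure = generate_structure(default_params(name, seed=seed))
        req = required_activities(structure)
        expected = EXPECTED_ACTIVITIES[name]
        if req.names != expected:
            raise SystemExit(
                f"{name} (seed {seed}): activity set {sorted(req.names)} "
                f"!= expected {sorted(expected)}; pick another seed"
            )
        if req.unmapped:
            raise SystemExit(f"{name}: unmapped classes {req.unmapped}")
        result = digest(structure, req)
        if result.completeness != 1.0:
            raise SystemExit(
                f"{name}: required activities digest to "
                f"{result.completeness:.3f}, expected 1.0"
            )
        save_structure(structure, outdir / f"{name}.json")
        print(f"{name:<32} {len(structure):>3} residues  "
              f"{len(req)} activities  OK")


if __name__ == "__main__":
    main()
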