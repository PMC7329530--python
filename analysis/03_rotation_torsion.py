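#!/usr/bin/env python
"""Summarize recovered rotation and torsion against the exact ground truth.

Reads the tracking outputs of 02_track_engines.py plus the phantom ground
truth and writes results/summary/rotation_torsion.json with per-engine
end-systolic values and errors.
"""

import json
from pathlib import Path

from tagtwist.io import read_torsion_json, write_json

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    summary = {}
    for label in ("clean", "noisy"):
        truth = json.loads((ROOT / "phantom" / label / "ground_truth.json").read_text())
        es = truth["end_systole_index"]
        truth_ap = truth["rotation_deg"]["apical"][es]
        truth_ba = truth["rotation_deg"]["basal"][es]
        block = {"truth": {"apical": truth_ap, "basal": truth_ba,
                           "torsion": truth_ap - truth_ba}}
        for engine in ("harp", "ffd"):
            tor = read_torsion_json(ROOT / "tracking" / label / f"torsion_{engine}.json")
            block[engine] = {
                "apical": tor.end_systolic_apical_rotation,
                "basal": tor.end_systolic_basal_rotation,
                "torsion": tor.end_systolic_torsion,
                "apical_error": tor.end_systolic_apical_rotation - truth_ap,
                "basal_error": tor.end_systolic_basal_rotation - truth_ba,
            }
        summary[label] = block
    out = ROOT / "summary"
    out.mkdir(parents=True, exist_ok=True)
    write_json(out / "rotation_torsion.json", summary)
    print(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
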