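#!/usr/bin/env python
"""Generate the study-sized synthetic cohort.

Simulates 10 subjects x 2 visits of raw dual-wavelength recordings on the
four-condition session design (movement-evoked pain noninjured/injured, VR
relaxation, VR distraction), with physiological noise, motion artifacts,
planted pre->post neural effects, behavioral change scores, and the
feasibility pattern of 5 missing plus 1 invalid recording. Bundles land in
scratch/cohort/ (large), the ground-truth sidecar and a session summary in
results/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from vrnirs.io import write_recording
from vrnirs.synth import simulate_cohort

ROOT = Path(__file__).resolve().parents[1]
SEED = 20260101

MISSING = [(0, "pre", "injured"), (1, "post", "relaxation"),
           (2, "pre", "distraction"), (3, "post", "noninjured"),
           (4, "pre", "relaxation")]
INVALID = [(5, "post", "distraction")]


def main() -> int:
    out = ROOT / "scratch" / "cohort"
    res = ROOT / "results"
    res.mkdir(exist_ok=True)

    cohort = simulate_cohort(n_subjects=10, seed=SEED, missing=MISSING,
                             invalid=INVALID)
    n = 0
    for s in cohort.subjects:
        for visit, rec in (("pre", s.pre), ("post", s.post)):
            write_recording(rec, out / f"{s.subject_id}_{visit}")
            n += 1
    cohort.behavioral.to_csv(out / "behavioral.csv", index=False)
    pd.DataFrame(
        [(s.subject_id, s.age, s.time_since_injury_d, s.injury_type)
         for s in cohort.subjects],
        columns=["subject", "age", "time_since_injury_d", "injury_type"],
    ).to_csv(out / "covariates.csv", index=False)
    cohort.session_log.to_csv(out / "session_log.csv", index=False)

    link = cohort.truth["link"]
    sidecar = {
        "seed": SEED,
        "n_subjects": 10,
        "pre_betas": cohort.truth["pre_betas"].tolist(),
        "post_betas": cohort.truth["post_betas"].tolist(),
        "neural_change": cohort.truth["neural_change"].tolist(),
        "link": {"condition": link.condition, "channel": link.channel,
                 "instrument": link.instrument, "r": link.r},
        "behavioral_clip_fraction": cohort.truth["clip_fraction"],
    }
    (res / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))

    print(f"wrote {n} recording bundles to {out}")
    print(f"session log: {len(cohort.session_log)} scheduled recordings "
          f"({(cohort.session_log.status == 'missing').sum()} planted missing, "
          f"{(cohort.session_log.status == 'invalid').sum()} planted invalid)")
    print(f"planted brain-behavior link: channel {link.channel} "
          f"{link.condition} beta change vs {link.instrument}, r={link.r}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
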