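"""Simulate the synthetic two-group longitudinal cohort.

Generates the demo study: 9 control and 7 irradiated subjects imaged at 1M
and 6M post-irradiation (T2w, 30-direction DWI, pre/post-contrast T2*), with
a corpus-callosum contraction + MD drop planted at 1M and a cortical
expansion + CBV drop at 6M. Image volumes are written under scratch/ (they
are regenerable binaries); the study inventory goes to results/.

Run from the repository root:  python analysis/01_simulate_cohort.py [--seed N]
"""

import argparse
import json
from pathlib import Path

from morphorad.cohort import CohortDesign, make_cohort
from morphorad.validation import demo_study_design


def demo_design(seed: int = 0) -> CohortDesign:
    """The scaled demo study: half the acquisition resolution per axis, with
    DWI and T2* volumes included so the quantitative stages have inputs."""
    return demo_study_design(seed=seed, include_microstructure=True)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="scratch/demo_cohort")
    args = ap.parse_args()

    ds = make_cohort(demo_design(args.seed), args.out, seed=args.seed)
    Path("results").mkdir(exist_ok=True)
    ds.metadata.to_csv("results/cohort_metadata.csv", index=False)
    n_irr = (ds.metadata.group == "irradiated").sum()
    n_ctl = (ds.metadata.group == "control").sum()
    print(f"wrote {len(ds.metadata)} imaging sessions ({n_ctl} control, {n_irr} irradiated) to {ds.root}")
    planted = {
        sid: e["timepoints"]
        for sid, e in ds.truth["subjects"].items() if e["group"] == "irradiated"
    }
    example = next(iter(planted.values()))
    print("example planted irradiated effects:",
          json.dumps({tp: v["applied_volume_ratios"] for tp, v in example.items()}))


if __name__ == "__main__":
    main()
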