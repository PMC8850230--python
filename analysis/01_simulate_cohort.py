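"""Generate the synthetic study cohort.

Writes a seeded 13-control / 40-case image cohort (512 x 512 at 5 um/px;
controls are fine Gaussian fields, sigma 2 px; cases coarse fields, sigma
8 px, with dark flow-void spots), its manifest, and a per-subject CFD table
drawn from the published sector group parameters.  Images are binary scratch
artefacts and live under scratch/; the manifest and CFD table are the
text inputs consumed by the later steps.
"""

import json
import sys
from dataclasses import asdict
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
COHORT_DIR = ROOT / "scratch" / "cohort"
SEED = 0

from octatex import image_io, synthetic_data  # noqa: E402


def main() -> None:
    COHORT_DIR.mkdir(parents=True, exist_ok=True)
    images, manifest = synthetic_data.make_texture_cohort(
        n_control=13, n_case=40, master_seed=SEED
    )
    for img, rel in zip(images, manifest["image_path"]):
        image_io.save_image(img, COHORT_DIR / rel)
    manifest.to_csv(COHORT_DIR / "manifest.csv", index=False)
    cfd = synthetic_data.make_cfd_cohort(synthetic_data.CfdCohortParams(seed=SEED))
    cfd.to_csv(COHORT_DIR / "cfd.csv", index=False)
    provenance = {
        "master_seed": SEED,
        "n_control": 13,
        "n_case": 40,
        "control_params": asdict(synthetic_data.CONTROL_PARAMS),
        "case_params": asdict(synthetic_data.CASE_PARAMS),
    }
    (COHORT_DIR / "provenance.json").write_text(json.dumps(provenance, indent=2))
    print(f"wrote {len(images)} images + manifest + CFD table to {COHORT_DIR}")
    print(f"CFD records: {len(cfd)} rows over {cfd['sector'].nunique()} sectors")


if __name__ == "__main__":
    sys.exit(main())
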