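import numpy as np
import pytest

from octatex import grading, synthetic_data, texture

SIGMA_LADDER = (2.0, 4.0, 8.0)
N_LADDER_SEEDS = 20
N_SEPARATION_SEEDS = 20


@pytest.fixture(scope="session")
def sigma_ladder_curves():
    """Radial curves for Gaussian fields over a sigma ladder x seed batch.

    Shared by the correlation-length-recovery and zero-crossing
    monotonicity checks so the fields are generated once.
    """
    out = {}
    for sigma in SIGMA_LADDER:
        curves = []
        for seed in range(N_LADDER_SEEDS):
            params = synthetic_data.TextureParams(
                kernel_sigma_px=sigma, seed=seed
            )
            img = synthetic_data.gaussian_field(params)
            curves.append(texture.curve_from_image(img))
        out[sigma] = curves
    return out


@pytest.fixture(scope="session")
def separation_runs():
    """Oriented PC1 scores of seeded 10-control + 10-case synthetic cohorts.

    Controls are fine fields (sigma 2 px), cases coarse fields (sigma 8 px)
    with dark flow-void spots.  Returns per-seed (control, case) score
    arrays.
    """
    runs = []
    for master_seed in range(N_SEPARATION_SEEDS):
        images, _ = synthetic_data.make_texture_cohort(
            n_control=10, n_case=10, master_seed=master_seed
        )
        curves = [texture.curve_from_image(img) for img in images]
        g = grading.grade_cohort(curves)
        groups = np.asarray(g.groups)
        runs.append(
            (g.scores_pc1[groups == "control"], g.scores_pc1[groups == "case"])
        )
    return runs
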