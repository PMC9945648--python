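import numpy as np
import pytest

from dcewex import (
    AcquisitionSchedule,
    PhantomSpec,
    RelaxationContext,
    make_phantom,
    pca_aif,
    simulate_dce,
)
from dcewex.t1map import vfa_fit


@pytest.fixture(scope="session")
def schedule():
    return AcquisitionSchedule()


@pytest.fixture(scope="session")
def ctx():
    return RelaxationContext(r1=3.3, R10=0.5, M0=1000.0)


@pytest.fixture(scope="session")
def phantom_bundle(schedule, ctx):
    """One full 64-cubed phantom realization at SNR 100, simulated once.

    Provides the ground truth, the noisy 4D DCE data, the VFA volumes,
    the true AIF and the pipeline-estimated T1/M0 and AIF, shared by
    the AIF, fitting and end-to-end tests.
    """
    spec = PhantomSpec(snr=100.0, seed=3)
    phantom = make_phantom(spec, seed=3)
    dce, vfa, aif_true, sigma = simulate_dce(phantom, schedule, ctx, spec, seed=3)

    # candidate pool for AIF extraction: the vessel plus a random 1% of
    # the volume (mimics a crude vascular pre-mask)
    cand = phantom["vessel"] | (
        np.random.default_rng(0).random(phantom["vessel"].shape) < 0.01
    )
    T1c, M0c, validc, _ = vfa_fit(vfa["volumes"][cand], vfa["angles"], schedule.tr_s)
    aif_est, selected = pca_aif(
        dce[cand], schedule,
        np.where(validc, T1c, spec.t1_tumor_s),
        np.where(validc, M0c, spec.m0), ctx,
        top_fraction=phantom["vessel"].sum() / cand.sum(),
    )
    return {
        "spec": spec,
        "phantom": phantom,
        "dce": dce,
        "vfa": vfa,
        "aif_true": aif_true,
        "aif_est": aif_est,
        "sigma": sigma,
        "cand_mask": cand,
        "selected": selected,
    }
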