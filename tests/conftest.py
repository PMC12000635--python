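import pytest

from t1knn import preprocess as pp
from t1knn.phantom import PhantomSpec, generate_phantom, simulate_study


@pytest.fixture(scope="session")
def spec48():
    return PhantomSpec(shape=(48, 48, 48), seed=7)


@pytest.fixture(scope="session")
def phantom48(spec48):
    """Noiseless ground-truth phantom shared across tests."""
    return generate_phantom(spec48)


@pytest.fixture(scope="session")
def study48(spec48):
    """Noisy (WM SNR 50) rendered study for the 48^3 phantom."""
    return simulate_study(spec48)


def normalize_study(study):
    """WM-normalize a simulated study's MPRAGE and FLAIR volumes."""
    ph = study["phantom"]
    p_wm = ph.prob_maps["wm"]
    mpr = pp.normalize_by_wm(
        study["mprage"], pp.wm_reference_mean(study["mprage"], p_wm), "mprage"
    )
    fla = pp.normalize_by_wm(
        study["flair"], pp.wm_reference_mean(study["flair"], p_wm), "flair"
    )
    return mpr, fla
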