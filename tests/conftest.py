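import pytest

from isletdose.decay_data import load_spectrum
from isletdose.sphere_mc import SphereGeometry, compute_sphere_svalue

#: Table-style scenario facts reused across test modules:
#: (nuclide, diameter um, tau_one_islet, A0, printed islet self-dose mGy)
ISLET_SELF_DOSE_CASES = [
    ("In-111", 50.0, 1.67e-9, 150.0, 15.4),
    ("In-111", 100.0, 1.34e-8, 150.0, 18.2),
    ("In-111", 400.0, 8.56e-7, 150.0, 37.9),
    ("Ga-68", 50.0, 2.80e-11, 75.0, 0.07),
    ("Ga-68", 100.0, 2.24e-10, 75.0, 0.13),
    ("Ga-68", 400.0, 1.44e-8, 75.0, 0.51),
]

MC_HISTORIES = 300_000
MC_SEED = 20_170_109


@pytest.fixture(scope="session")
def in111():
    return load_spectrum("In-111")


@pytest.fixture(scope="session")
def ga68():
    return load_spectrum("Ga-68")


@pytest.fixture(scope="session")
def sphere_svalues(in111, ga68):
    """Self-dose S-values for every (nuclide, diameter) the scenarios use."""
    spectra = {"In-111": in111, "Ga-68": ga68}
    results = {}
    for nuclide, diameter, *_ in ISLET_SELF_DOSE_CASES:
        results[(nuclide, diameter)] = compute_sphere_svalue(
            spectra[nuclide],
            SphereGeometry(diameter_um=diameter),
            n_histories=MC_HISTORIES,
            seed=MC_SEED,
        )
    return results


@pytest.fixture(scope="session")
def sphere_table(sphere_svalues):
    return {k: v.s_mgy_per_mbqh for k, v in sphere_svalues.items()}
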