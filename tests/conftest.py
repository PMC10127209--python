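import numpy as np
import pytest

from confland import gamd_reweight as gr
from confland import synthetic_data as sd


@pytest.fixture(scope="session")
def harmonic_surface():
    """V = 2 (x - 3)^2 on [0, 6] at 300 K (kT ~ 0.596 kcal/mol)."""
    return sd.harmonic_surface(k=2.0, x0=3.0, domain=(0.0, 6.0))


@pytest.fixture(scope="session")
def harmonic_ensemble(harmonic_surface):
    """50k frames from the boosted harmonic well (E=2, k0=0.5), seed 7."""
    boost = sd.BoostModel(total=sd.BoostComponent(E=2.0, k0=0.5))
    return sd.gen_boosted_ensemble(harmonic_surface, boost, n_frames=50_000, seed=7)


@pytest.fixture(scope="session")
def toy_set():
    """Noiseless toy trajectory alternating closed/open over 10 frames."""
    return sd.gen_toy_trajectory(
        10, state_schedule=["closed", "open"] * 5, noise_sd=0.0, seed=0
    )


@pytest.fixture()
def toy_files(toy_set, tmp_path):
    pdb = tmp_path / "toy.pdb"
    dcd = tmp_path / "toy.dcd"
    csv = tmp_path / "toy.csv"
    toy_set.write_pdb(pdb)
    toy_set.write_dcd(dcd)
    toy_set.write_csv(csv)
    return {"pdb": pdb, "dcd": dcd, "csv": csv}


def harmonic_quadrature_pmf(edges, k=2.0, x0=3.0, kT=gr.kT_at(300.0)):
    """Independent oracle: Boltzmann bin probabilities by fine quadrature."""
    probs = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        x = np.linspace(lo, hi, 400)
        probs.append(np.trapezoid(np.exp(-k * (x - x0) ** 2 / kT), x))
    p = np.asarray(probs)
    return p / p.sum()
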