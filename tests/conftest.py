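import numpy as np
import pytest
from hypothesis import settings

from memsense.io import AnalysisConfig
from memsense.synthetic import SyntheticBilayerParams, gen_buckled_bilayer, gen_planar_bilayer

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def planar_params():
    return SyntheticBilayerParams(n_per_leaflet=92, target_apl=65.0, thickness=4.0, seed=11)


@pytest.fixture(scope="session")
def planar_traj(planar_params):
    """Jitter-free 92-lipid-per-leaflet flat bilayer."""
    return gen_planar_bilayer(planar_params)


@pytest.fixture(scope="session")
def planar_frame(planar_traj):
    return planar_traj.frames[0]


@pytest.fixture(scope="session")
def buckled_params():
    return SyntheticBilayerParams(
        n_per_leaflet=400,
        target_apl=65.0,
        thickness=4.0,
        buckle_amplitude=1.0,
        buckle_wavelength=20.0,
        seed=12,
    )


@pytest.fixture(scope="session")
def buckled_traj(buckled_params):
    """Jitter-free single-mode buckle: h(x) = 1.0 sin(2*pi*x/20)."""
    return gen_buckled_bilayer(buckled_params)


@pytest.fixture(scope="session")
def buckled_frame(buckled_traj):
    return buckled_traj.frames[0]


@pytest.fixture(scope="session")
def buckled_surfaces(buckled_frame, config):
    """Fitted upper/lower surface models of the buckled fixture."""
    from memsense.peptide import assign_leaflets
    from memsense.surface import fit_surface

    labels = assign_leaflets(buckled_frame)
    names = buckled_frame.bead_names.astype(str)
    mx, my = config.fourier_modes
    out = {}
    for leaflet in ("upper", "lower"):
        mask = (names == "PO4") & np.array(
            [labels[int(m)] == leaflet for m in buckled_frame.molecule_ids]
        )
        out[leaflet] = fit_surface(
            buckled_frame.positions[mask],
            (buckled_frame.box[0], buckled_frame.box[1]),
            mx,
            my,
            leaflet=leaflet,
        )
    return out
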