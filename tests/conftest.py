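import numpy as np
import pytest

from tmsdose import efield as ef
from tmsdose import headmodel as hm
from tmsdose import neuron as nr
from tmsdose import population as pop
from tmsdose import synthdata as sd


@pytest.fixture(scope="session")
def head():
    return hm.build_head()


@pytest.fixture(scope="session")
def coil():
    return ef.default_coil()


@pytest.fixture(scope="session")
def morphology():
    return nr.generate_reduced_l5_morphology(seed=1)


@pytest.fixture(scope="session")
def tree(morphology):
    return nr.discretize(morphology)


@pytest.fixture(scope="session")
def biophys():
    return nr.default_biophys()


@pytest.fixture(scope="session")
def waveform():
    return nr.biphasic_waveform()


@pytest.fixture(scope="session")
def m1_placement(head):
    surf = head.surfaces[sd.M1]
    center_dir = np.asarray(surf.spec.patch_center_direction, float)
    target = surf.vertices[hm.nearest_vertex(surf, head.scalp_radius_mm * center_dir)]
    return hm.place_coil(head, target, 45.0)


def uniform_psi(tree, direction, magnitude=1.0):
    """Quasipotentials for a uniform field of given mV/mm along direction."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d) * magnitude
    return nr.quasipotentials(tree, lambda p: np.tile(d, (len(p), 1)))


@pytest.fixture(scope="session")
def m1_threshold_maps(head, coil, m1_placement, tree, biophys, waveform):
    """Small with/without-synapse threshold maps on the reference head,
    shared by the population and dosing tests."""
    surf = head.surfaces[sd.M1]
    rc = hm.nearest_vertex(surf, m1_placement.center)
    cells = pop.place_cells(head, sd.M1, rc, target_count=40, seed=7)
    syn = pop.weak_synapse_for(tree, biophys)
    out = {}
    for ws in (False, True):
        out[ws] = pop.threshold_map_for_participant(
            "ref", head, sd.M1, cells, coil, m1_placement, tree, biophys,
            waveform, with_synapse=ws, synapse=syn if ws else None)
    out["cells"] = cells
    out["weak_synapse"] = syn
    return out
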