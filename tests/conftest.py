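import numpy as np
import pytest

from obpdyn.model_io import Atom, Structure
from obpdyn.synthetic import (GeneratorConfig, antiparallel_sheet, ideal_helix,
                              make_reference)


@pytest.fixture(scope="session")
def reference_structure() -> Structure:
    """Default 119-residue synthetic helical bundle."""
    return make_reference(GeneratorConfig())


@pytest.fixture(scope="session")
def helix25() -> Structure:
    return ideal_helix(25)


@pytest.fixture(scope="session")
def sheet() -> Structure:
    return antiparallel_sheet(8)


@pytest.fixture
def ca_only_chain() -> Structure:
    """119 residues with a single CA each, on a straight line."""
    atoms = [Atom(i + 1, "CA", "C", "ALA", i + 1, "A", np.array([3.8 * i, 0.0, 0.0]))
             for i in range(119)]
    return Structure(atoms, title="CA-only chain")


def rigid_transform(coords: np.ndarray, axis, angle_deg: float, shift) -> np.ndarray:
    """Rotate about a unit axis through the origin, then translate."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(t) * K + (1 - np.cos(t)) * (K @ K)
    return coords @ R.T + np.asarray(shift, float)
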