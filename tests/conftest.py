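import numpy as np
import pytest

from brainshift.block_matching import BlockMatchConfig, block_match_all
from brainshift.features import FeatureConfig, select_registration_points
from brainshift.fem import Material, bcc_mesh_from_labels
from brainshift.nemnrr import NEMConfig, nemnrr_register
from brainshift.pbnrr import PBNRRConfig, register_sparse
from brainshift.phantom import (
    GaussianBump,
    PhantomSpec,
    make_phantom,
    true_forward_displacements,
)

MATERIALS = {1: Material(3000.0, 0.45), 2: Material(10.0, 0.1),
             3: Material(3000.0, 0.45)}


@pytest.fixture(scope="session")
def materials():
    return MATERIALS


@pytest.fixture(scope="session")
def default_phantom():
    """Default 64^3 phantom: 3 mm Gaussian bump, textured, no resection."""
    spec = PhantomSpec(seed=1)
    pre, labels, truth, intra = make_phantom(spec)
    return {"spec": spec, "pre": pre, "labels": labels, "truth": truth,
            "intra": intra}


@pytest.fixture(scope="session")
def brain_mesh(default_phantom):
    return bcc_mesh_from_labels(default_phantom["labels"], 6.0)


@pytest.fixture(scope="session")
def pbnrr_pipeline(default_phantom, brain_mesh):
    """Feature selection + block matching + PBNRR solve on the default phantom."""
    ph = default_phantom
    pts = select_registration_points(
        ph["pre"],
        FeatureConfig(selection_fraction=0.15, mask=np.asarray(ph["labels"].data) > 0,
                      margin=(6, 6, 6)),
    )
    matches, skipped = block_match_all(
        ph["pre"], ph["intra"], pts, BlockMatchConfig()
    )
    result = register_sparse(brain_mesh, MATERIALS, matches, PBNRRConfig())
    g = true_forward_displacements(ph["truth"], brain_mesh.vertices)
    return {"points": pts, "matches": matches, "skipped": skipped,
            "result": result, "truth_vertex_disp": g, "mesh": brain_mesh}


@pytest.fixture(scope="session")
def nemnrr_no_cavity(default_phantom, brain_mesh):
    ph = default_phantom
    cfg = NEMConfig(bgi_threshold=30.0, inner_max=15)
    return nemnrr_register(ph["pre"], ph["intra"], brain_mesh, MATERIALS, cfg)


@pytest.fixture(scope="session")
def resection_case():
    """Phantom with an 8 mm spherical cavity plus the NEMNRR solve."""
    spec = PhantomSpec(seed=3, resection=True, resection_radius=8.0)
    pre, labels, truth, intra = make_phantom(spec)
    mesh = bcc_mesh_from_labels(labels, 4.0)
    cfg = NEMConfig(bgi_threshold=30.0, inner_max=8)
    result = nemnrr_register(pre, intra, mesh, MATERIALS, cfg)
    return {"spec": spec, "pre": pre, "labels": labels, "truth": truth,
            "intra": intra, "mesh": mesh, "result": result, "cfg": cfg}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
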