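import numpy as np
import pandas as pd
import pytest

from pcmorph.io import Arbor


def build_arbor(nodes, species=None, ml=None):
    """nodes: list of (node_id, type_label, x, y, z, radius, parent_id)."""
    return Arbor(
        node_id=np.array([n[0] for n in nodes]),
        parent_id=np.array([n[6] for n in nodes]),
        xyz=np.array([[n[2], n[3], n[4]] for n in nodes], dtype=float),
        radius=np.array([n[5] for n in nodes], dtype=float),
        structure=np.array([n[1] for n in nodes], dtype=object),
        species=species,
        molecular_layer_thickness=ml,
    )


def make_map(labels, spacing=100.0, species="human", foliar=None, lobule=None,
             hemisphere="vermis", individual="ind-1", x=None):
    """Build a cell map from five-class labels ('Normative', 'V-Split', ...)."""
    n = len(labels)
    morph = ["Normative" if l == "Normative" else l.split("-", 1)[1] for l in labels]
    orient = ["NA" if l == "Normative"
              else ("Vertical" if l.startswith("V") else "Horizontal")
              for l in labels]
    if x is None:
        x = np.arange(n, dtype=float) * spacing
    return pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n)],
        "x": np.asarray(x, dtype=float),
        "y": np.zeros(n),
        "morph_type": morph,
        "orientation": orient,
        "foliar": foliar if foliar is not None else ["Bank"] * n,
        "lobule": lobule if lobule is not None else ["L5"] * n,
        "hemisphere": hemisphere,
        "individual": individual,
        "species": species,
    })


def random_map(rng, n, species="human", spacing_mean=100.0):
    classes = ("Normative", "V-Split", "H-Split", "V-Poly", "H-Poly")
    labels = [classes[i] for i in rng.integers(0, 5, size=n)]
    x = np.cumsum(rng.uniform(10.0, 3.0 * spacing_mean, size=n))
    foliar = [("Gyrus", "Bank", "Sulcus")[i] for i in rng.integers(0, 3, size=n)]
    return make_map(labels, species=species, foliar=foliar, x=x)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
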