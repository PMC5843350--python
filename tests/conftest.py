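import numpy as np
import pytest

from epistrat.mechanics import MechanicsParams
from epistrat.tissue import Cell, Tissue


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cell(cell_id, stage, center, k=6, spread=1.2, rng=None, **kw):
    rng = rng or np.random.default_rng(cell_id + 7)
    pts = rng.standard_normal((k, 3)) * spread + np.asarray(center, dtype=float)
    return Cell(
        cell_id=cell_id,
        stage=stage,
        elements=pts,
        adherent=np.zeros(k, dtype=bool),
        **kw,
    )


def make_tissue(centers_stages, box=(100.0, 100.0, 100.0), periodic=False, k=6, rng=None):
    t = Tissue(box=box, periodic_xy=periodic)
    for i, (center, stage) in enumerate(centers_stages):
        t.cells.append(make_cell(i, stage, center, k=k, rng=rng))
    t.next_cell_id = len(t.cells)
    return t


@pytest.fixture
def two_cell_tissue(rng):
    return make_tissue([((45.0, 50.0, 50.0), 0), ((55.0, 50.0, 50.0), 1)], rng=rng)


@pytest.fixture
def mech_params():
    return MechanicsParams()
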