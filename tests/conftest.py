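import numpy as np
import pytest

from windsift.grid import Grid, Mask


def make_template(rows=8, cols=8, cell=100.0, x0=0.0, crs="EPSG:5070"):
    """A zeroed analysis grid with its top-left corner at (x0, rows*cell)."""
    return Grid(
        data=np.zeros((rows, cols), dtype=np.uint8),
        x_origin=x0,
        y_origin=rows * cell,
        cell_size=cell,
        crs=crs,
    )


def mask_from_array(arr, cell=100.0):
    arr = np.asarray(arr, dtype=bool)
    template = make_template(*arr.shape, cell=cell)
    return Mask.from_bool(template, arr)


@pytest.fixture
def template():
    return make_template()


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
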