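import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import hybridcyc as h


@pytest.fixture(scope="session")
def layout():
    return h.default_layout()


@pytest.fixture(scope="session")
def small_scene(layout):
    """A 30-cell noise-free tissue scene: table, truth, rendered stacks."""
    cfg = h.tissue_population_config(n_cells=30, hybrid_fraction=0.1, seed=3)
    table, truth = h.generate_cell_population(cfg, layout)
    rc = h.RenderConfig(image_shape=(180, 180), seed=7)
    stacks, channels = h.render_image_rounds(table, truth, layout, rc)
    return {"table": table, "truth": truth, "stacks": stacks, "channels": channels, "rc": rc}


def disk_labels(shape, centers, radius):
    """Independent rasterizer: integer label image of disks (1-based labels)."""
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for i, (cy, cx) in enumerate(centers, start=1):
        labels[(yy - round(cy)) ** 2 + (xx - round(cx)) ** 2 <= radius**2] = i
    return labels
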