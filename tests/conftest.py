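import numpy as np
import pytest

from cellsegnet.simulate import ColonyMovieSpec, generate_bacteria_colony_movie


@pytest.fixture(scope="session")
def colony():
    """A small colony movie with two divisions, shared across tests."""
    spec = ColonyMovieSpec(initial_cells=2, relative_growth_rate=0.08,
                           division_length=36.0, frames=12, seed=3)
    movie, gt = generate_bacteria_colony_movie(spec)
    return spec, movie, gt


def relabel_frames(masks):
    """Replace globally consistent instance ids with per-frame labels, as a
    tracker would receive them."""
    out = []
    for m in masks:
        fresh = np.zeros_like(m)
        for i, lbl in enumerate(np.unique(m)[1:], start=1):
            fresh[m == lbl] = i
        out.append(fresh)
    return out


@pytest.fixture(scope="session")
def relabeled_colony_masks(colony):
    _, _, gt = colony
    return relabel_frames(gt.instance_masks)
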