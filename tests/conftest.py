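import numpy as np
import pytest

from migvar import (
    Bump,
    CellScript,
    DesignSpec,
    GenerativeParams,
    MaskMovieSpec,
    generate_hierarchical_dataset,
    generate_mask_movie,
)

CANONICAL_SIGMA2 = {
    "lab": 4.0,
    "person": 1.0,
    "experiment": 0.5,
    "replicate": 0.25,
    "cell": 2.0,
    "residual": 2.0,
}

#: Study design scaled to 10 cells x 24 time points for fast simulations.
SCALED_DESIGN = DesignSpec(n_cells_per_replicate=10, n_timepoints=24)


def canonical_params(seed: int, delta: float = 3.0) -> GenerativeParams:
    s = CANONICAL_SIGMA2
    return GenerativeParams(
        beta0=1.0,
        delta=delta,
        sigma2_lab=s["lab"],
        sigma2_person=s["person"],
        sigma2_experiment=s["experiment"],
        sigma2_replicate=s["replicate"],
        sigma2_cell=s["cell"],
        sigma2_residual=s["residual"],
        seed=seed,
    )


@pytest.fixture(scope="session")
def scaled_table():
    """One scaled-design draw with ground truth, shared across tests."""
    table, truth = generate_hierarchical_dataset(SCALED_DESIGN, canonical_params(7))
    return table, truth


@pytest.fixture
def two_cell_movie():
    """Five frames, one drifting cell with a bump plus one static cell."""
    spec = MaskMovieSpec(
        n_frames=5,
        image_size=(80, 80),
        pixel_size=1.0,
        cells=(
            CellScript(
                label=1,
                center=(25.0, 25.0),
                radius=8.0,
                velocity=(2.0, 0.0),
                bumps=(Bump(frame=2, radius=3.0, angle=0.5),),
            ),
            CellScript(label=2, center=(58.0, 58.0), radius=7.0),
        ),
    )
    return generate_mask_movie(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
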