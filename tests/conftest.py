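import numpy as np
import pytest

import axonquant as aq
from axonquant.scene import FiberPath, SyntheticScene


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def straight_scene(
    n_y: int = 5,
    n_z: int = 4,
    length_um: float = 317.44,
    spacing_um: float = 20.0,
    lesion_um: float = 150.0,
    **param_overrides,
) -> SyntheticScene:
    """A scene of straight, well-separated axial fibers spanning the window."""
    defaults = dict(
        n_fibers=n_y * n_z,
        nerve_radius_um=60.0,
        conduit_inner_radius_um=70.0,
        conduit_wall_um=5.0,
        axial_extent_um=length_um + 1,
        lesion_position_um=lesion_um,
        autofluorescence_level=0.0,
        read_noise_sd=0.0,
        photon_scale=0.0,
        seed=0,
    )
    defaults.update(param_overrides)
    params = aq.SceneParams(**defaults)
    x = np.arange(0.0, length_um + 0.5, 1.0)
    ys = (np.arange(n_y) - (n_y - 1) / 2) * spacing_um
    zs = (np.arange(n_z) - (n_z - 1) / 2) * spacing_um
    fibers = []
    for y in ys:
        for z in zs:
            pts = np.column_stack([x, np.full_like(x, y), np.full_like(x, z)])
            fibers.append(FiberPath(pts, "through"))
    return SyntheticScene(params, tuple(fibers), lesion_um)


@pytest.fixture
def noiseless_params():
    """Default scene parameters with rendering noise and conduit texture off."""
    return dict(autofluorescence_level=0.0, read_noise_sd=0.0, photon_scale=0.0)


@pytest.fixture(scope="session")
def masking_setup():
    """One small conduit render with a classifier trained on its ground truth,
    plus an independent held-out render. Shared across masking tests."""
    from axonquant.masking import extract_features, train_classifier
    from axonquant.render import ground_truth_labels, make_grid_for_scene

    scales = (2.0, 5.0)
    axial = (800.0, 1200.0)

    def build(seed):
        scene = aq.generate_scene(aq.SceneParams(seed=seed))
        grid = make_grid_for_scene(scene, axial)
        stack = aq.render_stack(scene, axial)
        labels = ground_truth_labels(scene, grid)
        return scene, grid, stack, labels

    train = build(500)
    feats = extract_features(train[2], scales)
    model = train_classifier(feats, train[3], seed=1, scales_um=scales)
    held = build(501)
    return {"scales": scales, "axial": axial, "model": model, "train": train, "held": held}
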