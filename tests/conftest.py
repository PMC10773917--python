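import numpy as np
import pytest

from ednet.architecture import assemble_ednet
from ednet.data import generate_synthetic_dataset
from ednet.training import desk_scale_conditions, evaluate, train


def brute_force_pool(grid, mode):
    """Window-scan pooling oracle: explicit loops, no vectorisation."""
    grid = np.asarray(grid, dtype=float)
    h, w = grid.shape
    out = np.empty((h // 2, w // 2))
    for i in range(0, h, 2):
        for j in range(0, w, 2):
            window = [grid[i][j], grid[i][j + 1], grid[i + 1][j], grid[i + 1][j + 1]]
            out[i // 2, j // 2] = max(window) if mode == "max" else sum(window) / 4
    return out


@pytest.fixture(scope="session")
def desk_runs(tmp_path_factory):
    """Small-scale training runs for seeds 0..2, shared across tests.

    Each run: width-1/8 network, 48x48 input, noise-free fully-separable
    synthetic set (60 train / 15 test per class), 5 epochs.  Returns a dict
    seed -> (history, held-out EvalResult of the best checkpoint).
    """
    runs = {}
    for seed in (0, 1, 2):
        spec, net_cfg, train_cfg = desk_scale_conditions(seed)
        data_dir = tmp_path_factory.mktemp(f"desk_{seed}")
        manifest = generate_synthetic_dataset(spec, data_dir)
        net = assemble_ednet(net_cfg)
        history = train(net, manifest, train_cfg)
        result = evaluate(net, manifest.split("test"), train_cfg.batch_size)
        runs[seed] = (history, result)
    return runs
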