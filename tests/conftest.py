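import numpy as np
import pytest

from extractopt.datasets import load_table1_pbd, load_table2_bbd


@pytest.fixture(scope="session")
def table1():
    return load_table1_pbd()


@pytest.fixture(scope="session")
def table2():
    return load_table2_bbd()


def grid_argmax(coeffs: np.ndarray, resolution: float = 0.001,
                lo: float = -1.0, hi: float = 1.0):
    """Brute-force maximizer of a 10-coefficient quadratic over the box at the
    given resolution, by a coarse vectorized sweep refined locally to the
    target resolution.  Independent of the package's optimizers."""
    from extractopt.rsm import quadratic_model_matrix

    def sweep(lows, highs, step):
        axes = [np.arange(l, h + step / 2, step) for l, h in zip(lows, highs)]
        g = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([a.ravel() for a in g])
        vals = quadratic_model_matrix(pts) @ coeffs
        k = int(np.argmax(vals))
        return pts[k], float(vals[k])

    coarse = 0.02
    best, _ = sweep([lo] * 3, [hi] * 3, coarse)
    lows = np.maximum(best - coarse, lo)
    highs = np.minimum(best + coarse, hi)
    return sweep(lows, highs, resolution)
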