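import numpy as np
import pytest

from cardiosynth.phantom import make_phantom_params, render_phantom


def phantom_pairs(view: str, n: int, resolution: int, seed: int,
                  variability: float = 0.2):
    """Deterministic list of (frame, masks) phantom pairs."""
    seeds = np.random.SeedSequence(seed).generate_state(n)
    out = []
    for s in seeds:
        params = make_phantom_params(view, int(s), variability)
        out.append(render_phantom(params, resolution))
    return out


@pytest.fixture(scope="session")
def sax_pairs_64():
    return phantom_pairs("SAX", 30, 64, seed=101)


@pytest.fixture(scope="session")
def sax_frames_32():
    return [p[0] for p in phantom_pairs("SAX", 40, 32, seed=202)]
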