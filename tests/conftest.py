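import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20160601)


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Naive flood-fill oracle: list of components as pixel-coordinate sets."""
    neighbours = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        neighbours += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    rows, cols = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    components = []
    for i, j in zip(*np.nonzero(mask)):
        if seen[i, j]:
            continue
        stack, comp = [(int(i), int(j))], []
        seen[i, j] = True
        while stack:
            r, c = stack.pop()
            comp.append((r, c))
            for dr, dc in neighbours:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc] and not seen[rr, cc]:
                    seen[rr, cc] = True
                    stack.append((rr, cc))
        components.append(frozenset(comp))
    return components
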