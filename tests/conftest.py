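import numpy as np
import pytest

from ccmorph.contour_io import ContourPair, Polyline
from ccmorph.synthetic import SimulationConfig, preset_effectmaps, simulate_cohort


@pytest.fixture
def parallel_pair() -> ContourPair:
    """Horizontal boundaries at y = +1 and y = -1 over x = 0..9: constant
    separation 2 mm, so cdv = 1 at every position."""
    x = np.linspace(0.0, 9.0, 10)
    upper = Polyline(np.column_stack([x, np.ones_like(x)]))
    lower = Polyline(np.column_stack([x, -np.ones_like(x)]))
    return ContourPair("toy", upper, lower)


def random_smooth_pair(rng: np.random.Generator, subject_id: str = "rand") -> ContourPair:
    """A smooth random open contour pair (low-frequency Fourier wiggles)."""
    t = np.linspace(0.0, 1.0, 80)
    x = 60.0 * t
    base = 8.0 * np.sin(np.pi * t)
    wig = sum(
        rng.normal(0, 1.0) * np.sin(np.pi * (k + 1) * t) for k in range(3)
    )
    half = 1.5 + 0.5 * np.cos(2 * np.pi * t) + 0.2 * np.abs(wig)
    upper = np.column_stack([x, base + half])
    lower = np.column_stack([x, base - half])
    return ContourPair(subject_id, Polyline(upper), Polyline(lower))


def source_arc_positions(vertices: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Arc-length coordinate of each point along the source polyline,
    located by orthogonal projection onto the nearest segment."""
    vertices = np.asarray(vertices, float)
    seg = np.diff(vertices, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    out = np.empty(len(points))
    for i, p in enumerate(points):
        rel = p - vertices[:-1]
        t = np.clip(np.einsum("ij,ij->i", rel, seg) / seg_len**2, 0.0, 1.0)
        d = np.linalg.norm(rel - t[:, None] * seg, axis=1)
        j = int(np.argmin(d))
        out[i] = cum[j] + t[j] * seg_len[j]
    return out


@pytest.fixture(scope="session")
def paper_like_cohort():
    """One simulated matched cohort with the paper_like effect preset."""
    config = SimulationConfig(seed=11)
    effects = preset_effectmaps(config.n_points)["paper_like"]
    pairs, records = simulate_cohort(config, effects)
    return config, effects, pairs, records
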