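import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_clean_config():
    """A small noiseless two-parasegment field with known distance models."""
    from hoxfish.config import DistanceModel, SimConfig, tiled_parasegments

    def make(seed=0, **overrides):
        kwargs = dict(
            seed=seed,
            field_size=(192, 128, 20),
            parasegments=tiled_parasegments(["compact", "open"], 192, 128),
            nuclei_per_ps=6,
            distance_model={
                ("compact", "ab"): DistanceModel("normal", 350, 70),
                ("compact", "ac"): DistanceModel("normal", 350, 70),
                ("open", "ab"): DistanceModel("normal", 700, 70),
                ("open", "ac"): DistanceModel("normal", 700, 70),
            },
        )
        kwargs.update(overrides)
        return SimConfig(**kwargs)

    return make


def brute_force_match(spots_a, spots_b, spots_c, radius_nm=1500.0):
    """Independent exhaustive triplet matcher used as oracle.

    Plain-loop nearest-neighbour search over full distance matrices, then
    the documented greedy one-to-one rule: candidates sorted by the larger
    anchor-partner distance (anchor index breaks ties), partners used once.
    Returns a set of (a_idx, b_idx, c_idx) index triples.
    """
    def dist(p, q):
        return sum((pi - qi) ** 2 for pi, qi in zip(p, q)) ** 0.5

    xa = [tuple(s.centroid) for s in spots_a]
    xb = [tuple(s.centroid) for s in spots_b]
    xc = [tuple(s.centroid) for s in spots_c]
    candidates = []
    for bi, pb in enumerate(xb):
        da = [dist(pb, p) for p in xa]
        dc = [dist(pb, p) for p in xc]
        ai = min(range(len(da)), key=lambda i: da[i])
        ci = min(range(len(dc)), key=lambda i: dc[i])
        if da[ai] <= radius_nm and dc[ci] <= radius_nm:
            candidates.append((max(da[ai], dc[ci]), bi, ai, ci))
    candidates.sort()
    used_a, used_c, out = set(), set(), set()
    for _, bi, ai, ci in candidates:
        if ai in used_a or ci in used_c:
            continue
        used_a.add(ai)
        used_c.add(ci)
        out.add((ai, bi, ci))
    return out


def random_spots(rng, n, box_nm=5000.0, channel="ch"):
    from hoxfish.spots import Spot

    return [Spot(channel_label=channel,
                 centroid=tuple(rng.uniform(0, box_nm, 3)),
                 peak_intensity=1.0, voxel_count=1) for _ in range(n)]
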