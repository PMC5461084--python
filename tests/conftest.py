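"""Shared fixtures: small deterministic scenes and the multi-seed study."""

from __future__ import annotations

import numpy as np
import pytest

import svddmap as sm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def two_class_halfplane(
    width=40, height=20, mixing_width=1, noise_sd=0.0, seam_col=20, seed=0
):
    """Left half target (code 0), right half outlier, vertical seam."""
    p = 3
    cov = (noise_sd**2) * np.eye(p)
    spec = sm.SceneSpec(
        n_bands=p,
        grid=(height, width),
        classes=[
            sm.ClassSignature("target", [1.0, 2.0, 3.0], cov, is_target=True),
            sm.ClassSignature("other", [3.0, 0.0, 1.0], cov),
        ],
        parcel_layout=sm.ParcelLayout(row_edges=[], col_edges=[seam_col]),
        mixing_width=mixing_width,
        seed=seed,
    )
    # parcel classes are drawn randomly: walk the seed until the layout is
    # target-left / outlier-right
    for trial in range(50):
        raster, truth = sm.generate_scene(spec)
        lab = truth.labels.labels
        if lab[0, 0] == 0 and lab[0, -1] == 1:
            return spec, raster, truth
        spec.seed += 1
    raise RuntimeError("could not realize half-plane layout")


@pytest.fixture
def halfplane():
    return two_class_halfplane(noise_sd=0.02, seed=3)


@pytest.fixture
def small_scene():
    """Compact 4-class scene for fast pipeline tests."""
    spec = sm.canonical_scene_spec(7)
    spec.grid = (100, 100)
    return (spec, *sm.generate_scene(spec))


@pytest.fixture(scope="session")
def multi_seed_study():
    """Full pipeline (w=3) on the canonical scene over 10 seeds, with
    window-based, size-matched random, and water-excluded validation."""
    results = {"window": [], "random": [], "no_water": []}
    for seed in range(10):
        spec = sm.canonical_scene_spec(seed)
        raster, truth = sm.generate_scene(spec)
        water = next(c for c, n in truth.labels.class_table.items() if n == "water")
        for mode, kwargs in [
            ("window", {}),
            ("random", {"validation_mode": "random"}),
            ("no_water", {"exclude_codes": (water,)}),
        ]:
            res = sm.run_oneclass_mapping(
                raster, truth.labels, spec.target_index, seed=seed, **kwargs
            )
            results[mode].append(res)
    return results
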