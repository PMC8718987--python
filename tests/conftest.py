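"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from nrpquant import calibration as cal
from nrpquant import densitometry as dens
from nrpquant.image_io import MembraneImage
from nrpquant.phantom import BrainPhantomSpec, DotBlotSpec, make_brain_phantom, make_dotblot


# ------------------------------------------------------------------ oracles

def brute_force_integrated_density(pixels, center, radius, background="none",
                                   inner_factor=1.2, outer_factor=1.8):
    """Independent per-pixel loop oracle for disk+annulus integrated density."""
    h, w = pixels.shape
    disk_vals, ann_vals = [], []
    for r in range(h):
        for c in range(w):
            d = ((r - center[0]) ** 2 + (c - center[1]) ** 2) ** 0.5
            if d <= radius:
                disk_vals.append(pixels[r, c])
            elif inner_factor * radius < d <= outer_factor * radius:
                ann_vals.append(pixels[r, c])
    b = float(np.median(ann_vals)) if background == "annulus_median" else 0.0
    return float(sum(disk_vals) - b * len(disk_vals)), len(disk_vals)


def wilcoxon_enumeration_oracle(a, b):
    """Exact two-sided rank-sum p by enumerating all C(n+m, n) arrangements."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # tie-free data assumed
    n, m = len(a), len(b)
    u_obs = sum(ranks[v] for v in a) - n * (n + 1) / 2
    mean_u = n * m / 2
    count = 0
    total = 0
    for idx in combinations(range(n + m), n):
        u = sum(i + 1 for i in idx) - n * (n + 1) / 2
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
        total += 1
    return u_obs, count / total


def series_from_image(img, truth) -> cal.CalibrationSeries:
    """Measure every phantom spot and assemble a calibration series."""
    levels = []
    for c, grp in truth.groupby("nominal"):
        ds = [
            dens.measure_spot(
                img, dens.SpotROI(r["row"], r["col"], r["roi_radius"], r["label"])
            ).integrated_density
            for _, r in grp.iterrows()
        ]
        levels.append((float(c), tuple(ds)))
    return cal.CalibrationSeries(tuple(sorted(levels)))


# ----------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def clean_dotblot():
    """Noiseless, background-free dot blot: truth and readout agree exactly."""
    spec = DotBlotSpec(replicate_cv=0.0, pixel_noise=0.0, background=(0, 0, 0), seed=1)
    img, truth = make_dotblot(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def standard_dotblot():
    """The standard validation-series phantom: 10 levels, 6 reps, 5% CV."""
    spec = DotBlotSpec(seed=1)
    img, truth = make_dotblot(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def symmetric_brain():
    """Lesion-free, noise-free brain print: exactly mirror-symmetric."""
    return make_brain_phantom(BrainPhantomSpec(lesion_depth=0.0, pixel_noise=0.0, seed=3))


@pytest.fixture(scope="session")
def lesioned_brain_clean():
    """Standard lesion (depth 0.3, sigma 30 px) with zero pixel noise."""
    return make_brain_phantom(BrainPhantomSpec(pixel_noise=0.0, seed=3))


@pytest.fixture(scope="session")
def lesioned_brain_noisy():
    """Standard lesion with pixel noise 0.01."""
    return make_brain_phantom(BrainPhantomSpec(pixel_noise=0.01, seed=3))


@pytest.fixture
def uniform_image():
    def _make(value=0.3, shape=(40, 60)):
        return MembraneImage(np.full(shape, value), is_reductive_scale=True)
    return _make
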