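"""Shared fixtures: small synthetic trees, waveforms and outlet sets.

Expensive transient solves are module- or session-scoped so the suite
stays fast; every randomized fixture is seeded.
"""

from __future__ import annotations

import numpy as np
import pytest

import pulmoflow as pf

# Windkessel resistance magnitudes representative of severe pulmonary
# hypertension (~1e8 Pa·s/m³ per branch) and the stroke-volume-over-
# pulse-pressure compliance estimate (~1.5e-8 m³/Pa total).
LPA_R = 169.29e6
RPA_R = 677.16e6
C_TOTAL = 1.5e-8


@pytest.fixture(scope="session")
def fluid() -> pf.FluidProperties:
    return pf.FluidProperties()


@pytest.fixture(scope="session")
def y_tree() -> pf.VascularTree:
    """Minimal 3-segment Y tree (one outlet per side)."""
    return pf.build_idealized_tree(2, 1, 1, 0.02, taper=0.2)


@pytest.fixture(scope="session")
def mid_tree() -> pf.VascularTree:
    """A 4-generation tree with segmental-caliber (~5 mm) outlets."""
    return pf.build_idealized_tree(4, 8, 6, 0.0303, taper=0.44)


@pytest.fixture(scope="session")
def stenosed_mid_tree(mid_tree) -> pf.VascularTree:
    return pf.apply_stenosis(mid_tree, pf.StenosisSpec("RPA", 0.438))


@pytest.fixture(scope="session")
def waveform() -> pf.InflowWaveform:
    return pf.generate_inflow_waveform(0.5732)


def outlets_for(tree, left=LPA_R, right=RPA_R, c_total=C_TOTAL):
    return pf.build_outlets(tree, left, right, c_total)


@pytest.fixture(scope="session")
def mid_outlets(stenosed_mid_tree):
    return outlets_for(stenosed_mid_tree)


def random_tree(rng: np.random.Generator) -> pf.VascularTree:
    """A random valid idealized tree (seeded by the caller's rng)."""
    generations = int(rng.integers(2, 5))
    if generations == 2:
        left = right = 1
    else:
        left = int(rng.integers(1, 9))
        right = int(rng.integers(1, 9))
    tree = pf.build_idealized_tree(
        generations,
        left,
        right,
        root_diameter=float(rng.uniform(0.015, 0.035)),
        taper=float(rng.uniform(0.2, 0.5)),
        length_ratio=float(rng.uniform(2.0, 4.0)),
    )
    if rng.random() < 0.5:
        candidates = [
            s.id for s in tree.segments.values() if s.parent_id is not None
        ]
        sid = candidates[int(rng.integers(len(candidates)))]
        tree = pf.apply_stenosis(
            tree, pf.StenosisSpec(sid, float(rng.uniform(0.2, 0.7)))
        )
    return tree


def random_outlets(tree, rng: np.random.Generator):
    return [
        pf.WindkesselOutlet(
            outlet_id=oid,
            resistance=float(rng.uniform(1e7, 1e9)),
            compliance=float(rng.uniform(1e-11, 1e-9)),
        )
        for oid in tree.outlet_ids
    ]
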