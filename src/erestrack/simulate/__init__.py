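"""Ground-truthed synthetic VAEM scene generation."""

from __future__ import annotations

import numpy as np

from ..config import SceneConfig
from .dynamics import simulate_dynamics
from .network import generate_er_network
from .placement import place_objects
from .render import Renderer, render
from .truth import (
    FREE,
    TRANSIT,
    CavityRegion,
    ColocTruth,
    GroundTruth,
    NetworkTruth,
)

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "NetworkTruth",
    "ColocTruth",
    "CavityRegion",
    "FREE",
    "TRANSIT",
    "generate_er_network",
    "place_objects",
    "simulate_dynamics",
    "render",
    "Renderer",
    "simulate_scene",
]


def stage_rngs(seed: int) -> dict[str, np.random.Generator]:
    """One child RNG per generation stage, derived from a single root seed."""
    children = np.random.SeedSequence(seed).spawn(4)
    names = ("network", "placement", "dynamics", "render")
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def simulate_scene(
    config: SceneConfig, seed: int | None = None
) -> tuple[GroundTruth, Renderer]:
    """Run network generation, placement and dynamics; return the truth
    plus a lazy frame renderer."""
    root = config.seed if seed is None else seed
    rngs = stage_rngs(root)
    network = generate_er_network(config, rngs["network"])
    initial = place_objects(config, network, rngs["placement"])
    truth = simulate_dynamics(config, initial, rngs["dynamics"])
    return truth, Renderer(config, truth, seed=root)
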