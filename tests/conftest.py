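"""Shared fixtures: synthetic structures with analytically known geometry."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from discopep.design_methods import DesignContext
from discopep.fixtures import (
    FixtureSpec,
    cloud_spec,
    paired_scaffold_spec,
    synth_structure,
)
from discopep.pathing import PathNode
from discopep.structure_io import Atom, Residue, read_structure


def context_from_spec(spec: FixtureSpec, **prepare_kwargs) -> DesignContext:
    structure = read_structure(synth_structure(spec), source_id=spec.name)
    return DesignContext.prepare(structure, **prepare_kwargs)


def make_residue(number: int, position, chain: str = "A", name3: str = "ALA") -> Residue:
    """A bare CA-only residue for geometry-level tests."""
    return Residue(
        chain_id=chain,
        author_number=number,
        insertion_code="",
        name3=name3,
        atoms=(Atom(name="CA", element="C", position=np.asarray(position, float)),),
    )


def random_path_nodes(n: int, seed: int, span: float = 30.0) -> list[PathNode]:
    """Random multi-residue path elements (distinct termini, G at midpoint)."""
    rng = np.random.default_rng(seed)
    nodes = []
    for i in range(n):
        start = rng.uniform(0.0, span, size=3)
        end = start + rng.uniform(-8.0, 8.0, size=3)
        nodes.append(
            PathNode(
                id=i,
                length=int(rng.integers(2, 5)),
                start_ca=start,
                end_ca=end,
                g_point=(start + end) / 2.0,
            )
        )
    return nodes


def brute_force_min_cost(nodes, allow_reverse: bool) -> float:
    """Independent path-cost oracle: enumerate every permutation and, for each
    fixed order, every orientation assignment via an exact two-state chain
    minimisation (equivalent to full orientation enumeration)."""
    n = len(nodes)
    termini = np.array(
        [[[node.start_ca, node.end_ca], [node.end_ca, node.start_ca]] for node in nodes]
    )  # (n, orient, in/out, 3); orient 1 = reverse
    n_orients = 2 if allow_reverse else 1
    cost = np.full((n, 2, n, 2), np.inf)
    for i, j in itertools.permutations(range(n), 2):
        for oi in range(n_orients):
            for oj in range(n_orients):
                cost[i, oi, j, oj] = np.linalg.norm(
                    termini[i, oi, 1] - termini[j, oj, 0]
                )
    best = np.inf
    for perm in itertools.permutations(range(n)):
        dp = np.zeros(n_orients)
        for a, b in itertools.pairwise(perm):
            dp = np.min(
                dp[:, None] + cost[a, :n_orients, b, :n_orients], axis=0
            )
        best = min(best, float(dp.min()))
    return best


@pytest.fixture(scope="session")
def cloud_ctx() -> DesignContext:
    return context_from_spec(cloud_spec(n=20, seed=3))


@pytest.fixture(scope="session")
def scaffold_ctx() -> DesignContext:
    return context_from_spec(paired_scaffold_spec(seed=0))


@pytest.fixture(scope="session")
def worked_example_ctx() -> DesignContext:
    from discopep.fixtures import flanking_demo_spec

    return context_from_spec(flanking_demo_spec())
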