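"""Shared fixtures: printed-count network reconstructions and small
synthetic data sets used across the suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

import micronet as m

# Pair-state counts of the two temperature networks, reconstructed from the
# published percentages and pair totals (complete networks: 2,288 and 576
# interacting pairs; common subnetworks: 1,530 and 447).  Directed link
# counts implied by these states reproduce the published link totals
# (2,409 / 581 complete; 1,625 / 450 common).
STATES_COMPLETE_30 = {"mutualism": 114, "commensalism": 2006, "antagonism": 7,
                      "amensalism": 161, "competition": 0}
STATES_COMPLETE_37 = {"mutualism": 2, "commensalism": 389, "antagonism": 1,
                      "amensalism": 182, "competition": 2}
STATES_COMMON_30 = {"mutualism": 88, "commensalism": 1335, "antagonism": 7,
                    "amensalism": 100, "competition": 0}
STATES_COMMON_37 = {"mutualism": 1, "commensalism": 290, "antagonism": 0,
                    "amensalism": 154, "competition": 2}

N_COMMON, N_SPEC_30, N_SPEC_37 = 145, 44, 17

_STATE_SIGNS = {
    "mutualism": (1, 1),
    "commensalism": (1, 0),
    "antagonism": (1, -1),
    "amensalism": (-1, 0),
    "competition": (-1, -1),
}


def _edges_for_pairs(pair_iter, state_counts):
    """Assign pair states to successive unordered pairs; yield directed edges."""
    edges = []
    for state, count in state_counts.items():
        s_ij, s_ji = _STATE_SIGNS[state]
        for _ in range(count):
            u, v = next(pair_iter)
            if s_ij:
                edges.append((u, v, s_ij))
            if s_ji:
                edges.append((v, u, s_ji))
    return edges


def build_condition_network(condition: str) -> m.SignedDirectedNetwork:
    """Signed directed network with the published pair-state composition.

    Common-subnetwork states are laid on pairs of shared nodes, the
    remainder on pairs touching condition-specific nodes, so the induced
    subnetwork on the shared nodes reproduces the published common-
    subnetwork statistics.
    """
    common = [f"c{i:03d}" for i in range(N_COMMON)]
    if condition == "30C":
        specific = [f"a{i:03d}" for i in range(N_SPEC_30)]
        states_total, states_common = STATES_COMPLETE_30, STATES_COMMON_30
    elif condition == "37C":
        specific = [f"b{i:03d}" for i in range(N_SPEC_37)]
        states_total, states_common = STATES_COMPLETE_37, STATES_COMMON_37
    else:
        raise ValueError(condition)
    nodes = common + specific
    common_pairs = itertools.combinations(common, 2)
    mixed_pairs = (p for p in itertools.combinations(nodes, 2)
                   if p[0] in set(specific) or p[1] in set(specific))
    edges = _edges_for_pairs(common_pairs, states_common)
    remainder = {s: states_total[s] - states_common[s] for s in states_total}
    assert all(v >= 0 for v in remainder.values())
    edges += _edges_for_pairs(mixed_pairs, remainder)
    return m.build_network(edges, nodes=nodes, condition=condition)


@pytest.fixture(scope="session")
def net_30c():
    return build_condition_network("30C")


@pytest.fixture(scope="session")
def net_37c():
    return build_condition_network("37C")


@pytest.fixture(scope="session")
def chain_ts():
    """Assembled, day-0-trimmed community series from the 3-genus chain."""
    cfg = m.chain_scenario(seed=0)
    latent = m.simulate_latent(cfg)
    obs = m.ObservationConfig(rng_seed=1000)
    tidy = m.observe(latent, obs, genus_labels=cfg.genus_labels)
    return m.drop_day0(m.assemble(tidy))


def noisy_ricker(seed, n=30, reps=3, r=2.9, noise=0.02):
    """Independent single-genus Ricker series (null-hypothesis material)."""
    rng = np.random.default_rng(seed)
    out = {}
    for rep in range(reps):
        x = np.empty(n)
        x[0] = rng.uniform(0.5, 1.5)
        for t in range(n - 1):
            x[t + 1] = x[t] * np.exp(r * (1 - x[t]) + rng.normal(0, noise))
        out[f"r{rep + 1}"] = x
    return out
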