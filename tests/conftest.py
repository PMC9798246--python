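"""Shared fixtures.

The expensive end-to-end experiment (10 synthetic structures x 3 defect
regimes) is simulated once per session; every test that needs
reconstructions, observable graphs or classification matrices reuses it.
"""
from __future__ import annotations

import numpy as np
import pytest

import graphtomo as gt
from graphtomo.features import features_frame
from graphtomo.similarity import classify

MASTER_SEED = 1


@pytest.fixture(scope="session")
def battery():
    return gt.fixture_battery(seed=MASTER_SEED)


@pytest.fixture(scope="session")
def sub_seeds(battery):
    children = np.random.SeedSequence(MASTER_SEED).spawn(len(battery))
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


@pytest.fixture(scope="session")
def experiment(battery, sub_seeds):
    """Simulate all three regimes once; classify at the relevant cutoffs.

    Returns a dict with the battery structures, the full-range
    reconstructions (kept for centroid-recovery checks), and a
    SimilarityMatrix per (regime, cutoff) pair.
    """
    names = [name for name, _ in battery]
    results: dict = {"names": names, "structures": dict(battery), "volumes_full": {}}

    control_feats = {}
    for dcut in (8.0, 9.0):
        graphs = [gt.build_contact_graph(s, dcut) for _, s in battery]
        control_feats[dcut] = features_frame(graphs, ids=names)
    results["control_features"] = control_feats

    wanted = {"full": (9.0,), "tumbled": (9.0,),
              "tumbled_missing_wedge": (8.0, 9.0)}
    for regime, cutoffs in wanted.items():
        observables = {dc: [] for dc in cutoffs}
        for (name, s), seed in zip(battery, sub_seeds):
            vol = gt.simulate_tomogram(s.as_atom_cloud(), regime=regime, seed=seed)
            if regime == "full":
                results["volumes_full"][name] = vol
            for dc in cutoffs:
                observables[dc].append(
                    gt.build_observable_graph(vol, dc, source_id=name))
        for dc in cutoffs:
            feats = features_frame(observables[dc], ids=names)
            results[(regime, dc)] = classify(feats, control_feats[dc],
                                             truth={n: n for n in names})
    return results
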