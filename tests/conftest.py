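from __future__ import annotations

from collections import defaultdict
from pathlib import Path

import pytest

from equiprio import fixtures
from equiprio.pipeline import run_pipeline
from equiprio.simulate import ScenarioConfig, bundle_config, generate_scenario


@pytest.fixture(scope="session")
def published():
    """The packaged published-table fixture bundle."""
    return fixtures.published_bundle()


@pytest.fixture(scope="session")
def scenario(tmp_path_factory):
    """One default synthetic scenario: (paths, truth)."""
    out = tmp_path_factory.mktemp("scenario")
    return generate_scenario(ScenarioConfig(seed=1), out)


def run_bundle(paths, out_dir, **params):
    """Run the full pipeline on a generated bundle."""
    return run_pipeline(bundle_config(paths, **params), out_dir)


def criterion_sets_from_calls(calls):
    """snp_id sets per criterion, from pipeline output."""
    sets = defaultdict(set)
    for c in calls:
        for name in ("protein_effect", "gerp_gt2", "constrained", "regulatory"):
            if getattr(c.flags, name):
                sets[name].add(c.snp_id)
    return dict(sets)
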