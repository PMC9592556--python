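import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from flexscore.scoring import ReferenceDistribution
from flexscore.synthdata import SyntheticSpec, build_structure, build_corpus_candidates


@pytest.fixture(scope="session")
def reference():
    return ReferenceDistribution.default()


@pytest.fixture(scope="session")
def helix_spec():
    return SyntheticSpec(ss_string="H" * 12, sequence="A" * 12, seed=7)


@pytest.fixture(scope="session")
def helix_model(helix_spec):
    return build_structure(helix_spec).models[0]


@pytest.fixture(scope="session")
def corpus_results():
    """Default 10-pair corpus, filtered and scored once per session."""
    from flexscore.compare import run_study

    candidates, manifest = build_corpus_candidates(seed=1)
    filters, records, summary = run_study(candidates)
    return candidates, manifest, filters, records, summary


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
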