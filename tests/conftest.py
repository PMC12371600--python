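"""Shared fixtures: small synthetic corpora with ground truth."""

from __future__ import annotations

import pytest

from mdslisten import SpellDictionary, SynthConfig, generate_corpus
from mdslisten import resources


@pytest.fixture(scope="session")
def small_corpus():
    """~80 users, ~1000 posts; enough structure for every stage."""
    return generate_corpus(SynthConfig(n_users=80, seed=11))


@pytest.fixture(scope="session")
def medium_corpus():
    """~400 users; used for recovery and distribution checks."""
    return generate_corpus(SynthConfig(n_users=400, seed=5))


@pytest.fixture(scope="session")
def dictionary():
    return SpellDictionary.from_file(resources.wordlist_path())
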