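import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from mirlitnet.lexicon import (MirnaLexiconEntry, default_disease_groups)
from mirlitnet.ner import AnnotatedAbstract, AnnotatedCorpus
from mirlitnet.synthetic import CorpusConfig


@pytest.fixture(scope="session")
def disease_groups():
    return default_disease_groups()


@pytest.fixture(scope="session")
def synth_lexicon():
    """Lexicon matching the default synthetic corpus vocabulary."""
    return [
        MirnaLexiconEntry(mid, f"MIMAT8{i + 1:06d}")
        for i, mid in enumerate(sorted(CorpusConfig().mirna_ids))
    ]


def make_annotated(abstract_entities, mirna_vocab=None, group_vocab=None):
    """Build an AnnotatedCorpus from [(mirna_set, group_set), ...] directly."""
    abstracts = tuple(
        AnnotatedAbstract(
            abstract_id=f"A{i}",
            mirna_ids=frozenset(ms),
            disease_groups=frozenset(gs),
        )
        for i, (ms, gs) in enumerate(abstract_entities)
    )
    mirnas = frozenset(mirna_vocab or {m for ms, _ in abstract_entities for m in ms})
    groups = frozenset(group_vocab or {g for _, gs in abstract_entities for g in gs})
    return AnnotatedCorpus(abstracts, mirnas, groups)
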