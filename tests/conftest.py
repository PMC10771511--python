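import pytest

from trialkg.arm_resolution import get_backend
from trialkg.outcome_typing import DictionaryExtractor
from trialkg.pipeline import run_pipeline
from trialkg.synthetic import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def backend():
    return get_backend("char3gram")


@pytest.fixture(scope="session")
def extractor():
    return DictionaryExtractor()


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    """A 30-trial synthetic corpus with its truth manifest."""
    out = tmp_path_factory.mktemp("corpus30")
    cfg = GeneratorConfig(n_trials=30, seed=3)
    corpus_dir, manifest = generate_corpus(cfg, out)
    return corpus_dir, manifest


@pytest.fixture(scope="session")
def small_result(small_corpus):
    corpus_dir, _ = small_corpus
    return run_pipeline(corpus_dir)


def analysis_stats(**overrides):
    """A stats dict in the shape the synthetic serializer expects."""
    base = {
        "p_value": None,
        "method": None,
        "param_name": None,
        "param_value": None,
        "ci_percent": None,
        "ci_lower": None,
        "ci_upper": None,
    }
    base.update(overrides)
    return base


def make_trial_xml(
    nct_id,
    arms,
    outcomes=(),
    events=(),
    conditions=(),
    intervention_types=("Drug",),
):
    """Hand-build a registry-dialect trial document for fixtures.

    ``arms``: list of (title, arm_group_type); ``outcomes``: list of
    (title, rank, [analysis dicts]) where each analysis dict has
    ``group_titles`` and ``stats`` (see :func:`analysis_stats`);
    ``events``: list of dicts with arm_title/event_title/category/severity/
    affected/at_risk (and optionally counts_as_attrs).
    """
    from trialkg.synthetic import _trial_xml

    trial = {
        "nct_id": nct_id,
        "conditions": list(conditions),
        "intervention_types": list(intervention_types),
        "arms": [{"title": t, "type": ty, "role": ""} for t, ty in arms],
        "outcomes": [
            {"title": t, "rank": rank, "analyses": list(analyses)} for t, rank, analyses in outcomes
        ],
        "events": [{"counts_as_attrs": True, **e} for e in events],
    }
    return _trial_xml(trial)
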