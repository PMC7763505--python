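import pytest

from notecode import CorpusSpec, generate_corpus, load_hierarchy


@pytest.fixture(scope="session")
def table():
    return load_hierarchy()


@pytest.fixture(scope="session")
def small_corpus():
    """A small, fast, well-separated synthetic corpus (4 codes over 3
    chapters with one sibling category pair)."""
    spec = CorpusSpec(
        n_records=240,
        code_set=["518.81", "518.82", "431", "770.8"],
        class_weights=[0.4, 0.3, 0.2, 0.1],
        mean_length=15.0,
        max_len=60,
        seed=7,
    )
    records, lexicon = generate_corpus(spec)
    return spec, records, lexicon
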