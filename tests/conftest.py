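import pytest

from pdblit import synthetic


@pytest.fixture(scope="session")
def lexicon():
    return synthetic.generate_lexicon(n_ids=120, n_blacklist=4, seed=7)


@pytest.fixture(scope="session")
def obo_bundle():
    text, manifest = synthetic.generate_obo(40, synonym_rate=0.4, seed=7, obsolete_extra=2)
    return text, manifest


@pytest.fixture(scope="session")
def small_corpus(lexicon, obo_bundle):
    """25 articles with planted mentions, decoys and ontology terms."""
    _, obo_manifest = obo_bundle
    spec = synthetic.PlantSpec(n_articles=25, seed=7)
    files, manifest = synthetic.generate_corpus(
        spec, lexicon, terms=synthetic.plantable_terms(obo_manifest))
    return files, manifest


@pytest.fixture(scope="session")
def parsed_articles(small_corpus):
    from pdblit import parse_jats
    files, manifest = small_corpus
    return {truth.pmc_id: parse_jats(files[f"PMC{truth.pmc_id}.xml"])
            for truth in manifest.articles}


MINIMAL_JATS = """<?xml version="1.0"?>
<article>
  <front><article-meta>
    <article-id pub-id-type="pmc">1483839</article-id>
    <title-group><article-title>A minimal article</article-title></title-group>
  </article-meta></front>
  <body><p>Hello</p></body>
</article>
"""


@pytest.fixture
def minimal_jats():
    return MINIMAL_JATS
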