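import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


DDI_FIXTURE_XML = """<?xml version="1.0" encoding="UTF-8"?>
<document id="d0">
  <sentence id="d0.s0" text="mineral oil reduces absorption of fat-soluble vitamins and vitamin d preparations.">
    <entity id="d0.s0.e0" type="drug" charOffset="0-10" text="mineral oil"/>
    <entity id="d0.s0.e1" type="group" charOffset="34-53" text="fat-soluble vitamins"/>
    <entity id="d0.s0.e2" type="group" charOffset="59-80" text="vitamin d preparations"/>
    <pair id="d0.s0.p0" e1="d0.s0.e0" e2="d0.s0.e1" ddi="true" type="mechanism"/>
    <pair id="d0.s0.p1" e1="d0.s0.e0" e2="d0.s0.e2" ddi="true" type="mechanism"/>
    <pair id="d0.s0.p2" e1="d0.s0.e1" e2="d0.s0.e2" ddi="false"/>
  </sentence>
</document>
"""

CHEMPROT_ABSTRACTS = (
    "10001\tAspirin inhibits COX2.\t"
    "Aspirin and salicylate block COX2 signalling. The enzyme remains active in Liver tissue.\n"
)

CHEMPROT_ENTITIES = (
    "10001\tT1\tCHEMICAL\t23\t30\tAspirin\n"
    "10001\tT2\tCHEMICAL\t35\t45\tsalicylate\n"
    "10001\tT3\tGENE-Y\t52\t56\tCOX2\n"
    "10001\tT4\tGENE-N\t73\t79\tenzyme\n"
)

CHEMPROT_RELATIONS = (
    "10001\tCPR:4\tY\tINHIBITOR\tArg1:T1\tArg2:T3\n"
    "10001\tCPR:4\tY\tINHIBITOR\tArg1:T2\tArg2:T3\n"
    "10001\tCPR:3\tN\tACTIVATOR\tArg1:T1\tArg2:T4\n"
)


@pytest.fixture
def ddi_xml_file(tmp_path):
    p = tmp_path / "ddi.xml"
    p.write_text(DDI_FIXTURE_XML, encoding="utf-8")
    return p


@pytest.fixture
def chemprot_files(tmp_path):
    a = tmp_path / "abstracts.tsv"
    e = tmp_path / "entities.tsv"
    r = tmp_path / "relations.tsv"
    a.write_text(CHEMPROT_ABSTRACTS, encoding="utf-8")
    e.write_text(CHEMPROT_ENTITIES, encoding="utf-8")
    r.write_text(CHEMPROT_RELATIONS, encoding="utf-8")
    return a, e, r


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tree_parse(rng, n):
    """Random single-rooted tree: each token's head is drawn uniformly
    among already-placed tokens (a random recursive tree)."""
    from relex.depgraph import DependencyParse

    heads = [0] * n
    for i in range(1, n):
        heads[i] = int(rng.integers(0, i)) + 1  # head among earlier tokens, 1-based
    tokens = [f"w{i}" for i in range(n)]
    return DependencyParse(tokens, heads)
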