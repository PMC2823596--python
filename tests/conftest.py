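import pytest

from guideflow import engine as en
from guideflow import fixtures as fx
from guideflow.mini_ontology import default_ontologies


@pytest.fixture(scope="session")
def ontologies():
    return default_ontologies()


@pytest.fixture(scope="session")
def sedation_set():
    return fx.make_sedation_flowcharts()


@pytest.fixture(scope="session")
def compiled_sedation(sedation_set):
    """{flow_id: (RuleFlowDocument, [RuleDefinition])} for all seven flows."""
    return fx.compile_sedation_set(sedation_set)


@pytest.fixture
def sedation_registry(compiled_sedation):
    def make():
        reg = en.FlowRegistry()
        for flow_id, (doc, _rules) in compiled_sedation.items():
            reg.register(flow_id, doc)
        return reg

    return make
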