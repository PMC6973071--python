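import pytest

from g4kit.synthetic import build_quadruplex, preset


@pytest.fixture(scope="session")
def preset_specs():
    return {name: preset(name) for name in ("parallel", "hybrid-ODN", "vloop-ODN1415", "vloop-typeB")}


@pytest.fixture(scope="session")
def preset_ensembles(preset_specs):
    return {name: build_quadruplex(spec) for name, spec in preset_specs.items()}


@pytest.fixture(scope="session")
def vloop_model(preset_ensembles):
    return preset_ensembles["vloop-ODN1415"].models[0]
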