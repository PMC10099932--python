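import pytest

from ninchi import annotations, macros


@pytest.fixture()
def header_registry():
    return annotations.standard_registry()


@pytest.fixture()
def macro_registry():
    reg = macros.MacroRegistry()
    reg.define("Anatase := 2O.Ti/k[Ir_1/amd]")
    reg.define("Sphere(%x) := Y(0,0)*%x")
    reg.define("Mystructure(%a,%b,%c) := core(%a) coating(%b) sphere(%c)")
    return reg
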