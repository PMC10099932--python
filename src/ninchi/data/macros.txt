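# Standard macro registry: Name(params) := body
Anatase := 2O.Ti/k[Ir_1/amd]
Sphere(%x) := Y(0,0)*%x
core(%a) := 1A/%a
coating(%b) := !/%b
sphere(%x) := /m[Y(0,0)]/s[%x]
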