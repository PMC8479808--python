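model,OutLys,InLys,APRIL,2AXM,1BFC
AA,-39.2,-36.9,-51.4,-86.6,-144.7
elongated_cg,-37.9,-36.8,-47.8,-98.3,-140.2
substituted_cg,-46.4,-30.8,-51.0,-90.1,-130.5
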