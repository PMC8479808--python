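dp,OutLys,InLys,APRIL,2AXM,1BFC
4,-24.2,-23.4,-25.6,-71.9,-65.7
6,-31.2,-27.6,-27.1,-84.8,-112.1
10,-35.9,-33.6,-42.8,-91.3,-126.2
16,-39.2,-36.9,-51.4,-86.6,-144.7
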