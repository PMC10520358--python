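ecm,passage_index,rate_pct
Matrigel,1,634.6
Matrigel,2,645.8
Matrigel,3,646.8
Matrigel,4,640.9
Matrigel,5,650.1
Matrigel,6,657.2
Alginate,1,465.1
Alginate,2,455.6
Alginate,3,477.2
Alginate,4,456.7
Alginate,5,476.3
Alginate,6,451.7
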