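@relation toy

@attribute f1 numeric
@attribute f2 numeric
@attribute f3 numeric
@attribute l1 {0,1}
@attribute l2 {0,1}

@data
1.0,2.5,-0.5,1,0
0.0,1.0,3.25,0,0
-2.0,0.5,1.5,1,1
4.0,-1.25,0.0,0,1
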