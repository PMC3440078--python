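group,sigma2_u,sigma2_s
preschool,0.0019,0.1576
schoolchildren,0.0025,0.0482
all,0.0019,0.1184
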