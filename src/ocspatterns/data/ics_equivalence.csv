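substance,bdp_equivalent_factor
beclometasone,1.0
budesonide,1.0
fluticasone_propionate,2.0
fluticasone_furoate,4.0
ciclesonide,2.5
mometasone,2.0
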