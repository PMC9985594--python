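substance,atc_code,ddd_mg
betamethasone,H02AB01,1.5
dexamethasone,H02AB02,1.5
methylprednisolone,H02AB04,7.5
prednisolone,H02AB06,10
prednisone,H02AB07,10
triamcinolone,H02AB08,7.5
hydrocortisone,H02AB09,30
cortisone,H02AB10,37.5
deflazacort,H02AB13,7.5
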