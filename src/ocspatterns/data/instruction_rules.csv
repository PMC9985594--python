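priority,pattern,verdict
10,long\s*term,long_term
20,continuous,long_term
30,maintenance,long_term
40,daily until review,long_term
50,repeat dispensing,long_term
60,do not stop,long_term
70,ongoing,long_term
100,for\s+(\d+|one|two|three|four|five|six|seven|eight|nine|ten|eleven|twelve|fourteen)\s+(?:days?|weeks?),intermittent
110,then stop,intermittent
120,reduc(?:e|ing),intermittent
130,taper,intermittent
140,short course,intermittent
150,rescue,intermittent
160,when required for (?:attack|exacerbation|flare),intermittent
170,stat and review,intermittent
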