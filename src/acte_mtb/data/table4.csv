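institution_type,country,overall,consultation,evidence,technology,access,implementation_rate_pct,imputed_not_sure
Academic,Australia,4.3,3.7,4.9,4.7,3.5,25,0
Academic,Austria,4.3,4.5,4.3,4.9,3.7,75,0
Academic,China,3.3,1.9,3.7,3.9,3.5,25,1
Academic,France,4.0,3.9,4.3,4.9,2.9,25,0
Academic,France,3.3,2.5,4.0,3.9,2.5,50,0
Academic,South Korea,3.0,1.3,3.9,4.3,2.9,100,0
Academic,United Kingdom,3.5,3.0,3.9,4.5,2.9,25,1
Academic,United States,3.9,4.5,2.9,5.0,2.9,50,0
Academic,United States,3.5,3.0,3.3,4.3,3.3,50,0
Community,Germany,2.0,2.5,1.0,2.3,2.7,25,0
Community,Germany,2.7,1.7,2.3,2.5,4.0,100,0
Community,Germany,3.9,2.0,5.0,4.3,3.3,75,0
Community,United Kingdom,3.3,3.0,3.0,4.0,2.7,25,1
Private,Germany,3.5,2.9,3.0,3.9,3.7,50,0
Private,United States,2.7,1.9,3.3,3.0,2.7,75,0
Specialized center,China,2.9,2.0,3.9,2.5,3.0,50,0
Specialized center,China,3.5,2.5,4.3,3.3,3.7,75,0
Specialized center,China,3.5,3.5,4.7,4.0,2.0,25,0
Specialized center,United Kingdom,3.3,3.9,1.9,4.3,2.7,25,1
Specialized center,United States,2.5,2.5,2.3,2.5,2.9,25,0
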