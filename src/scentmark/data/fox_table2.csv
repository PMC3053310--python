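fox,season,n_locations,gender,density_per_ha
A,Spring 1978,410,F,0.0257
B,Spring 1978,124,M,0.0257
C,Spring 1978,433,F,0.0257
D,Summer 1990,488,M,0.0324
E,Summer 1990,673,M,0.0324
F,Summer 1990,267,M,0.0324
E,Spring 1991,873,M,0.0442
F,Spring 1991,582,M,0.0442
G,Spring 1991,932,F,0.0442
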