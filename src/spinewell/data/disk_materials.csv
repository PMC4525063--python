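# Intervertebral-disk tissue parameters for the 1D osmo-poroelastic column.
# G, K in MPa; e0 = initial void ratio; k0 = initial permeability, mm^4/(N*s);
# M = dimensionless exponent of the strain-dependent permeability law
#   k = k0 * [e (1+e0) / (e0 (1+e))]^2 * exp(M ((1+e)/(1+e0) - 1))
# normalized so that k(e0) = k0 (Argoubi & Shirazi-Adl-type law).
# Sources: poroelastic disk characterizations by Malandrino and colleagues;
# permeability law after Argoubi & Shirazi-Adl.
tissue,G,K,e0,k0,M
AF,0.95,0.37,3.0,0.0002,8.5
NP,0.47,0.16,4.9,0.0009,8.5
CEP,8.55,10.10,4.0,0.0025,8.5
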