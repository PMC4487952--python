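land_category,yield_factor,equivalence_factor
arable,1.01,2.8
forest,1.57,1.1
pasture,3.17,0.5
fishery,3.17,0.2
built_up,1.01,2.8
fossil_energy,0,1.1
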