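# Phase offsets phi0 (degrees) for the six standard backbone couplings,
# J(phi) = A cos^2(phi + phi0) + B cos(phi + phi0) + C.
3J_CpCp: 0
3J_CpCb: 60
3J_HaCp: 120
3J_HNCp: 180
3J_HNCb: 60
3J_HNHa: -60
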