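label,ion_mode,multiplier,shift_da,charge
[M-H]-,negative,1,-1.00727646,-1
[M-H2O-H]-,negative,1,-19.01784114,-1
[M+Na-2H]-,negative,1,20.97466780,-1
[M+K-2H]-,negative,1,36.94860520,-1
[M+Cl]-,negative,1,34.96940126,-1
[M+HCOO]-,negative,1,44.99820285,-1
[M+CH3COO]-,negative,1,59.01385292,-1
[M(13C)-H]-,negative,1,-0.00392146,-1
[M+H]+,positive,1,1.00727646,1
[M+Na]+,positive,1,22.98922070,1
[M+K]+,positive,1,38.96315810,1
[M+NH4]+,positive,1,18.03382555,1
[M-H2O+H]+,positive,1,-17.00328822,1
[M(13C)+H]+,positive,1,2.01063146,1
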