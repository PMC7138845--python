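# Constitutive constants for swine descending colon tissue, one block per
# sample. C10 is the Neo-Hookean ground-matrix modulus; (k1l, k2l) govern the
# longitudinal collagen fiber family and (k1s, k2s) the pair of symmetric
# families inclined at +/- gamma from the circumferential direction.

label = #1
C10_Pa = 411
k1l_Pa = 1416
k2l = 80.63
k1s_Pa = 30
k2s = 164.22
gamma_deg = 44

label = #2
C10_Pa = 750
k1l_Pa = 28600
k2l = 4.55
k1s_Pa = 60
k2s = 916.94
gamma_deg = 55

label = #3
C10_Pa = 1873
k1l_Pa = 3290
k2l = 2.22
k1s_Pa = 144
k2s = 149.33
gamma_deg = 56

label = #4
C10_Pa = 1187
k1l_Pa = 201
k2l = 1.21
k1s_Pa = 2379
k2s = 19.97
gamma_deg = 50

label = #5
C10_Pa = 1591
k1l_Pa = 150
k2l = 1.15
k1s_Pa = 439
k2s = 39.82
gamma_deg = 49
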