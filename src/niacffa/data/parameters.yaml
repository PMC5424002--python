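# Published median parameter estimates (lean Sprague-Dawley and obese
# Zucker rats).  Units: time h, NiAc uM, insulin nM, FFA mM, amounts
# umol/kg.  t0 is the pump inactivation time (7 days).
lean:
  pk:
    ka: 4.27
    delta: 77.4
    Vmax1: 2.64
    Km1: 0.235
    Vmax2: 425.0
    Km2: 74.5
    Vp: 0.393
    Vt: 0.172
    Cld: 0.0511
    Synt: 0.213
    t0: 168.0
  insulin:
    I0: 0.188
    koutI: 6.58
    ImaxNI: 0.793
    IC50NI: 0.338
    n: 3.54
    ktolI: 0.646
    koutRI: 3.94
  ffa:
    F0: 0.707
    koutF: 428.0
    ImaxNF: 1.0
    IC50NF: 0.436
    m: 1.24
    ktolF: 1.21
    koutRF: 0.965
    kNF: 0.00654
    N50F: 3.05
    SNF: 0.807
    phi: 1.0
obese:
  pk:
    ka: 5.54
    delta: 62.4
    Vmax1: 164.0
    Km1: 18.9
    Vp: 0.323
    Synt: 0.168
    t0: 168.0
  insulin:
    I0: 3.26
    koutI: 10.8
    ImaxNI: 1.0
    IC50NI: 0.175
    n: 0.840
    ktolI: 0.125
    koutRI: 0.0612
    kNI: 0.0242
    N50I: 0.897
    gamma: 18.9
    SNI: 1.0
  ffa:
    F0: 1.14
    koutF: 173.0
    ImaxNF: 1.0
    IC50NF: 0.456
    m: 0.731
    ktolF: 0.708
    koutRF: 0.0165
    kNF: 0.0377
    N50F: 0.854
    SNF: 1.0
    phi: 8.83
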