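# 60-channel extended 10-20 montage (synthetic conventional stand-in layout)
# label,region  -- region by prefix rule; replace this file to remap
Fp1,frontal
Fpz,frontal
Fp2,frontal
AF3,frontal
AF4,frontal
F7,frontal
F5,frontal
F3,frontal
F1,frontal
Fz,frontal
F2,frontal
F4,frontal
F6,frontal
F8,frontal
FT7,temporal
FC5,central
FC3,central
FC1,central
FCz,central
FC2,central
FC4,central
FC6,central
FT8,temporal
T7,temporal
C5,central
C3,central
C1,central
Cz,central
C2,central
C4,central
C6,central
T8,temporal
TP7,temporal
CP5,parietal
CP3,parietal
CP1,parietal
CPz,parietal
CP2,parietal
CP4,parietal
CP6,parietal
TP8,temporal
P7,parietal
P5,parietal
P3,parietal
P1,parietal
Pz,parietal
P2,parietal
P4,parietal
P6,parietal
P8,parietal
PO7,occipital
PO5,occipital
PO3,occipital
POz,occipital
PO4,occipital
PO6,occipital
PO8,occipital
O1,occipital
Oz,occipital
O2,occipital
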