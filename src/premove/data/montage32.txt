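# Recommended 32-channel sensorimotor montage (synthetic stand-in:
# a 10-5 subset centered on the sensorimotor strip), one label per line.
# The reference electrode is declared separately in the pipeline config
# (default CPz). Edit freely to match your cap.
FC5
FC3
FC1
FCz
FC2
FC4
FC6
FCC5h
FCC3h
FCC1h
FCC2h
FCC4h
FCC6h
C5
C3
C1
Cz
C2
C4
C6
CCP5h
CCP3h
CCP1h
CCP2h
CCP4h
CCP6h
CP5
CP3
CP1
CP2
CP4
CP6
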