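# Selected feature subset for the three-class classifier (rank order).
C-score
rp
rsa
TOBD000102
SIMK990102
THOP960101
VENM980101
BONM030106
window_Y
MOOG990101
BONM030105
window_NonPolarAA
BETM990101
MIYS850103
window_ChargedAA
window_PosAA
BONM030101
window_F
SKOJ970101
window_R
window_D
AURR980118
LIWA970101
GARJ730101
BULH740101
OVEJ920103
QIAN880128
AURR980102
NADH010101
g2_g6
V_A
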