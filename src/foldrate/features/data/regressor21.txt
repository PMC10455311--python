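# Selected feature subset for the regression predictor (rank order).
rsa
C-score
rp
ZHAC000105
MOOG990101
ZHAC000102
BASU010101
window_T
SIMK990105
window_PolarAA
KESO980102
SIMK990102
window_G
window_Y
window_F
window_PosAA
window_V
window_D
SNEP660101
BULH740101
LAWE840101
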