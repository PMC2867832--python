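>MA0108.2 TBP
A [ 61 16 352 3 354 268 360 222 155 56 83 82 82 68 77 ]
C [ 145 46 0 10 0 0 3 2 44 135 147 127 118 107 101 ]
G [ 152 18 2 2 5 0 20 44 157 150 128 128 128 139 140 ]
T [ 31 309 35 374 30 121 6 121 33 48 31 52 61 75 71 ]
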