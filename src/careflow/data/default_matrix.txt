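# Default (severity, occurrence) -> risk-level grid, rows S=1..10 (top
# row S=1), columns O=1..10.  High: S>=9 any O, or S>=7 & O>=6, or
# S>=5 & O>=8.  Low: S<=2, or S<=4 & O<=3.  Medium elsewhere.
LLLLLLLLLL
LLLLLLLLLL
LLLMMMMMMM
LLLMMMMMMM
MMMMMMMHHH
MMMMMMMHHH
MMMMMHHHHH
MMMMMHHHHH
HHHHHHHHHH
HHHHHHHHHH
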