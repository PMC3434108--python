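# Four-region Ramachandran classification grid, 10 deg x 10 deg cells.
# Rows: phi bins from [-180,-170) to [170,180); columns: psi bins likewise.
# Labels: M most favoured, A additional allowed, G generously allowed,
# D disallowed.  Synthetic approximation of the classic four-region map:
# alpha (phi -160..-40, psi -70..0), beta (phi -170..-50, psi 90..180 with
# wrap to -180..-170) and left-handed alpha (phi 50..70, psi 20..60) cores
# marked M; one-cell dilation A; two further cells G; the rest D.  Both
# axes wrap.  Replace with any 36x36 {M,A,G,D} grid to change boundaries.
AAGGDDDDGGGGGGGGGGGGGDDDGGAAAAAAAAAA
MAGGDDDDGGAAAAAAAAAGGDDDGGAMMMMMMMMM
MAGGDDDDGGAMMMMMMMAGGDDDGGAMMMMMMMMM
MAGGDDDDGGAMMMMMMMAGGDDDGGAMMMMMMMMM
MAGGDDDDGGAMMMMMMMAGGDDDGGAMMMMMMMMM
MAGGDDDDGGAMMMMMMMAGGDDDGGAMMMMMMMMM
MAGGDDDDGGAMMMMMMMAGGDDDGGAMMMMMMMMM
MAGGDDDDGGAMMMMMMMAGGDDDGGAMMMMMMMMM
MAGGDDDDGGAMMMMMMMAGGDDDGGAMMMMMMMMM
MAGGDDDDGGAMMMMMMMAGGDDDGGAMMMMMMMMM
MAGGDDDDGGAMMMMMMMAGGDDDGGAMMMMMMMMM
MAGGDDDDGGAMMMMMMMAGGDDDGGAMMMMMMMMM
MAGGDDDDGGAMMMMMMMAGGDDDGGAMMMMMMMMM
AAGGDDDDGGAMMMMMMMAGGDDDGGAAAAAAAAAA
GGGGDDDDGGAAAAAAAAAGGDDDGGGGGGGGGGGG
GGGGDDDDGGGGGGGGGGGGGDDDGGGGGGGGGGGG
DDDDDDDDGGGGGGGGGGGGGDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDGGGGGGGGGGDDDDDDDDD
DDDDDDDDDDDDDDDDDGGGGGGGGGGDDDDDDDDD
DDDDDDDDDDDDDDDDDGGAAAAAAGGDDDDDDDDD
DDDDDDDDDDDDDDDDDGGAMMMMAGGDDDDDDDDD
DDDDDDDDDDDDDDDDDGGAMMMMAGGDDDDDDDDD
DDDDDDDDDDDDDDDDDGGAAAAAAGGDDDDDDDDD
DDDDDDDDDDDDDDDDDGGGGGGGGGGDDDDDDDDD
DDDDDDDDDDDDDDDDDGGGGGGGGGGDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
GGGGDDDDDDDDDDDDDDDDDDDDGGGGGGGGGGGG
GGGGDDDDGGGGGGGGGGGGGDDDGGGGGGGGGGGG
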