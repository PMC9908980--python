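# pattern -> kappa lookup for the 6-response up-down score
# X = withdrawal, O = no withdrawal.
# Bundled defaults follow the simplified up-down convention:
# kappa = +0.5 when the final response is O, -0.5 when it is X.
# Replace with tabulated values if your lab uses the full table.
OOOOOO	+0.5
OOOOOX	-0.5
OOOOXO	+0.5
OOOOXX	-0.5
OOOXOO	+0.5
OOOXOX	-0.5
OOOXXO	+0.5
OOOXXX	-0.5
OOXOOO	+0.5
OOXOOX	-0.5
OOXOXO	+0.5
OOXOXX	-0.5
OOXXOO	+0.5
OOXXOX	-0.5
OOXXXO	+0.5
OOXXXX	-0.5
OXOOOO	+0.5
OXOOOX	-0.5
OXOOXO	+0.5
OXOOXX	-0.5
OXOXOO	+0.5
OXOXOX	-0.5
OXOXXO	+0.5
OXOXXX	-0.5
OXXOOO	+0.5
OXXOOX	-0.5
OXXOXO	+0.5
OXXOXX	-0.5
OXXXOO	+0.5
OXXXOX	-0.5
OXXXXO	+0.5
OXXXXX	-0.5
XOOOOO	+0.5
XOOOOX	-0.5
XOOOXO	+0.5
XOOOXX	-0.5
XOOXOO	+0.5
XOOXOX	-0.5
XOOXXO	+0.5
XOOXXX	-0.5
XOXOOO	+0.5
XOXOOX	-0.5
XOXOXO	+0.5
XOXOXX	-0.5
XOXXOO	+0.5
XOXXOX	-0.5
XOXXXO	+0.5
XOXXXX	-0.5
XXOOOO	+0.5
XXOOOX	-0.5
XXOOXO	+0.5
XXOOXX	-0.5
XXOXOO	+0.5
XXOXOX	-0.5
XXOXXO	+0.5
XXOXXX	-0.5
XXXOOO	+0.5
XXXOOX	-0.5
XXXOXO	+0.5
XXXOXX	-0.5
XXXXOO	+0.5
XXXXOX	-0.5
XXXXXO	+0.5
XXXXXX	-0.5
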