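max_score
1.616161616
1.050505051
2.111111111
1.202020202
1.515151515
1.151515152
1.424242424
1.323232323
1.323232323
1.626262626
1
1.565656566
1.373737374
1.282828283
2.141414141
1.01010101
1.262626263
1.242424242
1.575757576
0.7474747475
1.141414141
1.656565657
0.9292929293
0.8181818182
0.9898989899
1.474747475
1.484848485
0.797979798
1.323232323
0.8484848485
1.191919192
1.191919192
1.252525253
2
1.787878788
1.404040404
0.7878787879
2.303030303
1.424242424
1.383838384
1.303030303
0.8484848485
1.949494949
0.9797979798
1.181818182
1.626262626
1.373737374
0.9393939394
0.9494949495
1.424242424
1.454545455
0.8888888889
0.9898989899
1.222222222
1.555555556
1.111111111
1.333333333
2.02020202
1.131313131
1.181818182
1.575757576
1.353535354
0.8484848485
1.272727273
0.8888888889
0.8888888889
1.232323232
0.9696969697
0.898989899
1.080808081
1.717171717
1.777777778
1.484848485
1.545454545
1.131313131
1.353535354
0.9898989899
0.8080808081
0.9898989899
0.8282828283
1.424242424
1.98989899
0.6060606061
1.595959596
2.646464646
1.151515152
0.8787878788
1.909090909
1.212121212
1.525252525
1.333333333
1.303030303
1.676767677
1.050505051
1.393939394
1.727272727
1.161616162
1.484848485
1.141414141
0.8686868687
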