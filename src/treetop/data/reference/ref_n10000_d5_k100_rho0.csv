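max_score
2.060606061
2.383838384
1.717171717
2.797979798
1.383838384
1.636363636
1.313131313
2.232323232
1.606060606
1.96969697
1.858585859
1.414141414
2.757575758
1.868686869
1.797979798
1.747474747
2.171717172
1.333333333
1.878787879
1.818181818
1.898989899
1.888888889
2.464646465
2.060606061
2.818181818
2.747474747
1.585858586
2.303030303
1.282828283
1.515151515
1.878787879
1.383838384
1.505050505
1.494949495
1.707070707
1.464646465
2.060606061
2.98989899
1.474747475
1.121212121
2.717171717
1.535353535
2.242424242
1.868686869
2.121212121
2.060606061
1.646464646
1.636363636
1.535353535
1.707070707
2.888888889
2.838383838
1.656565657
1.575757576
1.95959596
2.171717172
1.787878788
1.96969697
2.050505051
3.444444444
2.282828283
1.515151515
1.747474747
2.262626263
1.686868687
2.151515152
1.898989899
1.262626263
2.353535354
1.878787879
2.080808081
2.060606061
1.96969697
1.97979798
2.222222222
2.616161616
2.04040404
1.202020202
1.606060606
2.222222222
1.686868687
1.151515152
3.151515152
1.939393939
1.606060606
1.909090909
1.626262626
1.282828283
3.121212121
1.939393939
1.868686869
1.606060606
2.636363636
2.03030303
1.232323232
1.505050505
1.949494949
2.464646465
1.919191919
2.575757576
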