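max_score
2.535353535
3.515151515
2.202020202
3.04040404
3.919191919
3.747474747
3.373737374
3.808080808
2.171717172
2.646464646
3.95959596
3.03030303
2.424242424
2.01010101
3.01010101
3.04040404
3.696969697
2.939393939
2.383838384
3.03030303
3.707070707
2.606060606
2.343434343
3.121212121
2.515151515
5.909090909
2.585858586
2.171717172
2.525252525
2.202020202
3.666666667
3.111111111
2.262626263
3.111111111
2.95959596
3.474747475
2.707070707
2.595959596
3.96969697
2.353535354
3.808080808
3.202020202
2.909090909
3.02020202
3.464646465
2.494949495
2.707070707
1.808080808
4.484848485
3.303030303
2.242424242
3.424242424
2.505050505
3.828282828
2.707070707
3.95959596
5.060606061
3.707070707
3.383838384
3.484848485
6.151515152
2.262626263
2.171717172
2.838383838
2.484848485
4.404040404
2.95959596
2.676767677
3.585858586
3.181818182
1.858585859
3.595959596
4.252525253
2.343434343
2.737373737
2.484848485
1.97979798
2.242424242
4.343434343
4.04040404
3.707070707
4.777777778
2.535353535
2.535353535
2.585858586
2.848484848
4.434343434
5.04040404
3.484848485
4.04040404
2.919191919
2.727272727
2.434343434
2.232323232
3.151515152
5.545454545
2.96969697
3.060606061
2.787878788
2.505050505
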