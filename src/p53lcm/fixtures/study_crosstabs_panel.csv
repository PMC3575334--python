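DHPLC,DBH,RFLP-1,RFLP-2,cytology,count
1,1,1,0,1,1
1,1,1,1,1,257
1,1,1,1,2,28
1,1,1,2,1,29
1,1,1,2,2,1
1,1,1,3,1,6
1,1,1,3,2,1
1,1,2,1,2,1
1,1,2,2,1,15
1,2,1,2,1,2
1,2,3,3,1,3
1,3,1,2,1,2
1,3,1,3,1,2
1,3,3,1,1,1
1,3,3,2,1,1
1,3,3,3,1,2
1,3,3,3,2,1
2,1,1,2,1,6
2,1,1,2,2,1
2,1,2,1,1,1
2,1,3,1,1,1
2,1,3,3,1,1
2,2,1,1,1,6
2,2,1,2,1,6
2,2,2,2,1,344
2,2,2,2,2,21
2,2,2,3,1,9
2,3,2,1,1,1
2,3,2,2,1,5
2,3,3,3,1,3
2,3,3,3,2,1
3,1,1,1,1,3
3,2,1,2,1,1
3,2,1,3,1,1
3,2,2,1,1,1
3,2,2,2,1,1
3,3,2,3,1,13
3,3,2,3,2,1
3,3,3,3,1,126
3,3,3,3,2,5
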