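iop_lo,iop_hi,age_lo,age_hi,cct_lo,cct_hi,treat
24,26,0,55,0,555,0
24,26,0,55,555,590,0
24,26,0,55,590,1000000000.0,0
24,26,55,65,0,555,0
24,26,55,65,555,590,0
24,26,55,65,590,1000000000.0,0
24,26,65,80,0,555,1
24,26,65,80,555,590,0
24,26,65,80,590,1000000000.0,0
24,26,80,200,0,555,0
24,26,80,200,555,590,0
24,26,80,200,590,1000000000.0,0
26,28,0,55,0,555,1
26,28,0,55,555,590,0
26,28,0,55,590,1000000000.0,0
26,28,55,65,0,555,1
26,28,55,65,555,590,0
26,28,55,65,590,1000000000.0,0
26,28,65,80,0,555,1
26,28,65,80,555,590,1
26,28,65,80,590,1000000000.0,1
26,28,80,200,0,555,1
26,28,80,200,555,590,1
26,28,80,200,590,1000000000.0,1
28,30,0,55,0,555,1
28,30,0,55,555,590,1
28,30,0,55,590,1000000000.0,1
28,30,55,65,0,555,1
28,30,55,65,555,590,1
28,30,55,65,590,1000000000.0,1
28,30,65,80,0,555,1
28,30,65,80,555,590,1
28,30,65,80,590,1000000000.0,1
28,30,80,200,0,555,1
28,30,80,200,555,590,1
28,30,80,200,590,1000000000.0,1
30,1000000000.0,0,55,0,555,1
30,1000000000.0,0,55,555,590,1
30,1000000000.0,0,55,590,1000000000.0,1
30,1000000000.0,55,65,0,555,1
30,1000000000.0,55,65,555,590,1
30,1000000000.0,55,65,590,1000000000.0,1
30,1000000000.0,65,80,0,555,1
30,1000000000.0,65,80,555,590,1
30,1000000000.0,65,80,590,1000000000.0,1
30,1000000000.0,80,200,0,555,1
30,1000000000.0,80,200,555,590,1
30,1000000000.0,80,200,590,1000000000.0,1
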