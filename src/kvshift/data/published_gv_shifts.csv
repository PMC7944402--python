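mutant_label,has_2R,R362Q,R365Q,W454A,F416A,compound,concentration_uM,shift_mV,sem_mV,n,status,note
WT,False,False,False,False,False,Wu50,100,-25.5,1.4,5,measured,pH 9.0
R362Q,False,True,False,False,False,Wu50,100,-49.6,1.2,3,measured,pH 9.0
W454A,False,False,False,True,False,Wu50,100,-8.1,0.4,5,measured,pH 9.0
R362Q/W454A,False,True,False,True,False,Wu50,100,-41.0,4.4,5,measured,pH 9.0
R362Q/R365Q,False,True,True,False,False,Wu50,100,-25.5,4.6,5,measured,pH 9.0
R362Q/R365Q/W454A,False,True,True,True,False,Wu50,100,-24.7,3.0,6,measured,pH 9.0
2R,True,False,False,False,False,Wu50,100,-40.0,2.7,8,measured,pH 9.0
2R/R362Q,True,True,False,False,False,Wu50,100,-54.0,2.3,4,measured,pH 9.0
2R/W454A,True,False,False,True,False,Wu50,100,-40.1,,3,inferred,W454A shift plus the stated 32 mV increment of the 2R motif on this background; pH 9.0
2R/R362Q/W454A,True,True,False,True,False,Wu50,100,-56.6,5.8,4,measured,pH 9.0
R362Q/W454A/F416A,False,True,False,True,True,Wu50,100,,,,gmax_block,maximal conductance reduced by 83%; shift not reliably measurable
WT,False,False,False,False,False,Wu161,100,-9.8,1.1,5,measured,pH 7.4
W454A,False,False,False,True,False,Wu161,100,-5.6,0.8,4,measured,pH 7.4
R362Q,False,True,False,False,False,Wu161,100,-8.5,0.5,3,measured,pH 7.4
R362Q/R365Q,False,True,True,False,False,Wu161,100,-5.2,1.2,4,measured,pH 7.4
2R,True,False,False,False,False,Wu161,100,-32.0,2.7,6,measured,pH 7.4
R362Q/F416A/W454A,False,True,False,True,True,Wu161,100,0.0,,,eliminated,shift completely eliminated; mutant blocked at pH 9.0 so not testable with the pH-sensitive compound
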