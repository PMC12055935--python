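arc_deg,submodel,l,w,lambda_pct
90,sided,1/3,1/3,1.0
90,sided,1/3,2/3,3.0
90,sided,2/3,1/3,9.7
90,sided,2/3,2/3,16
90,centered,1/3,1/3,1.9
90,centered,1/3,2/3,1.8
90,centered,2/3,1/3,5.7
90,centered,2/3,2/3,17
90,through,1,1/3,20
90,through,1,2/3,45
270,sided,1/3,1/3,4.0
270,sided,1/3,2/3,6.5
270,sided,2/3,1/3,16
270,sided,2/3,2/3,25
270,centered,1/3,1/3,7.9
270,centered,1/3,2/3,8.5
270,centered,2/3,1/3,16
270,centered,2/3,2/3,29
270,through,1,1/3,19
270,through,1,2/3,51
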