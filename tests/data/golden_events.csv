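cell_id,pair_id,condition,t_cross_min,v_congress_um_per_min,window_used_min,aligned_ever,polar_initial,success_30min
reactivated_c0,p0,reactivated,7.000000,0.388586,6.000000,True,True,True
reactivated_c0,p1,reactivated,8.000000,0.365130,6.000000,True,True,True
reactivated_c0,p2,reactivated,5.000000,0.733621,5.000000,True,True,True
reactivated_c0,p3,reactivated,4.000000,0.524952,4.000000,True,True,True
reactivated_c0,p4,reactivated,0.000000,,,True,False,True
reactivated_c0,p5,reactivated,0.000000,,,True,False,True
reactivated_c1,p0,reactivated,6.000000,0.423632,6.000000,True,True,True
reactivated_c1,p1,reactivated,5.000000,0.563433,5.000000,True,True,True
reactivated_c1,p2,reactivated,14.000000,0.550465,6.000000,True,True,True
reactivated_c1,p3,reactivated,14.000000,0.210915,6.000000,True,True,True
reactivated_c1,p4,reactivated,0.000000,,,True,False,True
reactivated_c1,p5,reactivated,0.000000,,,True,False,True
inhibited_c0,p0,inhibited,,,,False,True,False
inhibited_c0,p1,inhibited,,,,False,True,False
inhibited_c0,p2,inhibited,10.000000,0.472572,6.000000,True,True,True
inhibited_c0,p3,inhibited,,,,False,True,False
inhibited_c0,p4,inhibited,0.000000,,,True,False,True
inhibited_c0,p5,inhibited,0.000000,,,True,False,True
inhibited_c1,p0,inhibited,,,,False,True,False
inhibited_c1,p1,inhibited,,,,False,True,False
inhibited_c1,p2,inhibited,,,,False,True,False
inhibited_c1,p3,inhibited,27.000000,0.502753,6.000000,True,True,True
inhibited_c1,p4,inhibited,0.000000,,,True,False,True
inhibited_c1,p5,inhibited,0.000000,,,True,False,True
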