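hotspot,chrom,left_marker,left_bp,right_marker,right_bp,ci_mb
QTL1A.1,1A,BS00056550_51,7294564,Kukri_c29655_239,9579957,2.3
QTL1B.2,1B,BS00072791_51,629262942,RFL_Contig2971_282,652455350,23.2
QTL2A.2,2A,IAAV880,755788335,Tdurum_contig50839_593,758514679,2.7
QTL2D.1,2D,Kukri_c16477_181,61979485,BS00067584_51,79416689,17.4
QTL3A.2,3A,Excalibur_c77321_69,737299578,Tdurum_contig31235_99,739397160,2.1
QTL3D.1,3D,Kukri_rep_c87658_1436,613696030,wsnp_Ex_c13629_21411429,609166802,4.5
QTL4A.2,4A,Excalibur_c74390_108,733915685,RAC875_c11702_1015,739524596,5.6
QTL5B.2,5B,BobWHIte_c47103_84,457342562,BS00039492_51,487602616,30.3
QTL5B.3,5B,GENE-3574_643,519148851,TA002629-0202,526576640,7.4
QTL5B.4,5B,wsnp_Ku_c3151_5892200,680852782,RAC875_c278_1801,683143220,2.3
QTL7A.1,7A,BS00024786_51,79542753,Kukri_rep_c101532_1046,84767559,5.2
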