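ethnicity,gene,locus_id,articles,major_minor,maf_percent,accumulated_samples,verdict,remaining_samples,odds_ratio,ci_low,ci_high,p_value,i2_percent,het_p_value
caucasian,VDR ApaI,rs7975232,7,C/A,45,1728,conclusive_null,0,0.90,0.72,1.36,0.9579,72,0.0017
caucasian,VDR BsmI,rs1544410,16,C/T,40,3620,conclusive_null,0,0.92,0.76,1.11,0.3841,64,0.0002
caucasian,IL6 G174C,rs1800795,9,G/C,42,7536,conclusive_null,0,0.94,0.87,1.01,0.0696,0,0.4418
caucasian,COL1A1 1245GT,rs1800012,8,C/A,19,1633,conclusive_null,0,1.27,0.71,2.27,0.4195,88,0.0000
caucasian,ESR1 PvuII,rs2234693,7,T/C,42,1726,conclusive_null,0,1.06,0.75,1.50,0.7298,82,0.0000
caucasian,ESR1 XbaI,rs9340799,7,A/G,31,1839,conclusive_null,0,0.87,0.58,1.31,0.5099,88,0.0000
caucasian,ESR2 RsaI,rs1256049,1,C/T,4,380,conclusive_null,0,1.30,0.81,2.10,0.2740,0,0.0000
caucasian,OPG T245G,rs3134069,2,A/C,4,596,conclusive_null,0,0.79,0.06,10.28,0.8551,68,0.0775
caucasian,VDR FokI,rs2228570,2,G/A,38,320,inconclusive,2305,0.96,0.69,1.34,0.8124,0,0.9999
caucasian,VDR TaqI,rs731236,5,A/G,40,1056,inconclusive,1547,1.34,0.94,1.92,0.1100,68,0.0141
caucasian,TGFb1 T869C,rs1800470,3,G/A,38,972,inconclusive,1656,1.03,0.58,1.83,0.9171,70,0.0339
caucasian,LRP5,rs3736228,2,C/T,13,481,inconclusive,4459,1.50,1.08,2.07,0.0149,0,0.6337
caucasian,ESR1 G2014A,rs2228480,1,G/A,17,570,inconclusive,3448,0.63,0.44,0.90,0.0117,0,0.0000
caucasian,ESR2 AluI,rs4986938,3,C/T,38,1097,inconclusive,1531,1.23,0.58,2.57,0.5899,94,0.0000
caucasian,OPG T950C,rs2073617,1,G/A,49,555,inconclusive,1395,0.93,0.73,1.17,0.5118,0,0.0000
caucasian,OPG A163G,rs3102735,2,T/C,13,624,inconclusive,4316,1.49,1.11,2.00,0.0079,0,0.4996
caucasian,OPG G1181C,rs2073618,1,G/C,47,555,inconclusive,2625,0.87,0.70,1.10,0.2523,0,0.0000
asian,VDR FokI,rs2228570,3,G/A,42,1300,conclusive_risk,0,1.44,1.22,1.70,0.0001,0,0.6276
asian,TGFb1 T869C,rs1800470,7,G/A,45,3472,conclusive_risk,0,1.35,1.10,1.65,0.0047,74,0.0007
asian,IGF1,rs2288377,6,A/T,29,4029,conclusive_risk,0,1.44,1.28,1.62,0.0001,0,0.5534
asian,IGF1,rs35767,7,G/A,37,4575,conclusive_risk,0,1.20,1.06,1.36,0.0032,47,0.0791
asian,ESR2 RsaI,rs1256049,1,C/T,40,1190,conclusive_protective,0,0.69,0.59,0.81,0.0001,0,0.0000
asian,COL1A1 1245GT,rs1800012,1,C/A,0.1,349,conclusive_null,0,0.83,0.56,1.23,0.3536,0,0.0000
asian,IGF1,rs5742612,6,A/G,29,4031,conclusive_null,0,1.10,0.97,1.26,0.1394,0,0.9564
asian,IL6 G174C,rs1800795,1,G/C,0.1,318,conclusive_null,0,0.61,0.05,7.28,0.6921,0,0.0000
asian,ESR1 XbaI,rs9340799,7,A/G,19,3123,conclusive_null,0,0.86,0.39,1.89,0.7093,97,0.0000
asian,ESR1 PvuII,rs2234693,7,T/C,40,3010,inconclusive,2075,0.82,0.55,1.22,0.3210,90,0.0000
asian,VDR ApaI,rs7975232,7,C/A,29,1804,inconclusive,1284,1.21,0.81,1.80,0.3442,81,0.0000
asian,VDR BsmI,rs1544410,19,C/T,6,2473,inconclusive,7345,1.01,0.64,1.60,0.9525,85,0.0000
asian,COL1A1 1997GT,rs1107946,2,C/A,30,580,inconclusive,2290,1.21,0.87,1.67,0.2564,25,0.2498
asian,ESR1 G2014A,rs2228480,3,G/A,20,798,inconclusive,2764,1.00,0.23,4.46,0.9955,97,0.0000
asian,ESR2 AluI,rs4986938,1,C/T,13,1303,inconclusive,4805,1.31,1.05,1.64,0.0164,0,0.0000
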