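probe_name	chrom	position
BIEC2_806771	3	101540587
BIEC2_806771_DUP	3	101540587
3-102641557-C-T	3	102641557
3-102641557-C-T_DUP	3	102641557
CUHSNP00061902	3	103779615
UKUL845	3	103779615
BIEC681989	3	104518656
BIEC681989_DUP	3	104518656
BIEC2_808543	3	107374136
GGP_100_BODY_SIZE_ECA3_F	3	107374136
GGP_100_BODY_SIZE_ECA3_F_2	3	107374136
GGP_103_BODY_SIZE_ECA11_F	11	23334511
GGP_103_BODY_SIZE_ECA11_F_2	11	23334511
BIEC2_438999	18	67027762
GGP_099_RACING_DISTANCE_MSTN_BIEC2-438999_F	18	67027762
GGP_099_RACING_DISTANCE_MSTN_BIEC2-438999_F_2	18	67027762
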