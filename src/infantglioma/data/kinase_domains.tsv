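gene	kd_start_exon	kd_end_exon
ALK	20	29
ROS1	36	41
NTRK1	13	17
NTRK2	15	20
NTRK3	14	19
MET	15	21
FGFR1	10	17
BRAF	11	18
RAF1	10	17
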