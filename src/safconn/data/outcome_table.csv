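area_a,area_b,outcome_label,provenance
8,9,RTP,population tractography outcome
8,46,RTP,population tractography outcome
8,9/46,RTP,population tractography outcome
8,44,RTP,population tractography outcome
8,45,RTP,reconciled with printed partition tallies
8,47,RTP,reconciled with printed partition tallies
8,10,RTP,reconciled with printed partition tallies
8,11,TN,population tractography outcome
8,13,FN,population tractography outcome
8,14,FN,population tractography outcome
8,24,TP,population tractography outcome
8,25,TN,population tractography outcome
8,32,RTP,population tractography outcome
9,46,RTP,population tractography outcome
9,9/46,RTP,population tractography outcome
9,44,RTP,reconciled with printed partition tallies
9,45,RTP,population tractography outcome
9,47,RTP,population tractography outcome
9,10,RTP,population tractography outcome
9,11,FP,population tractography outcome
9,13,FN,conflicting subsection labels; orbital/cingulate subsection adopted
9,14,FP,conflicting subsection labels; orbital/cingulate subsection adopted
9,24,TP,reconciled with printed partition tallies
9,25,TN,population tractography outcome
9,32,RTP,population tractography outcome
46,9/46,RTP,population tractography outcome
46,44,RTP,population tractography outcome
46,45,TP,population tractography outcome
46,47,RTP,population tractography outcome
46,10,TP,population tractography outcome
46,11,TN,population tractography outcome
46,13,TN,population tractography outcome
46,14,TN,population tractography outcome
46,24,FN,population tractography outcome
46,25,TN,population tractography outcome
46,32,FP,population tractography outcome
9/46,44,RTP,population tractography outcome
9/46,45,RTP,population tractography outcome
9/46,47,RTP,population tractography outcome
9/46,10,RTP,population tractography outcome
9/46,11,FP,conflicting subsection labels; orbital/cingulate subsection adopted
9/46,13,FN,population tractography outcome
9/46,14,FN,population tractography outcome
9/46,24,FP,conflicting subsection labels; orbital/cingulate subsection adopted
9/46,25,TN,population tractography outcome
9/46,32,FP,conflicting subsection labels; orbital/cingulate subsection adopted
44,45,RTP,population tractography outcome
44,47,RTP,population tractography outcome
44,10,TN,population tractography outcome
44,11,TN,population tractography outcome
44,13,TN,population tractography outcome
44,14,TN,population tractography outcome
44,24,FP,population tractography outcome
44,25,FP,reconciled with printed partition tallies
44,32,FP,population tractography outcome
45,47,RTP,population tractography outcome
45,10,TP,population tractography outcome
45,11,FP,population tractography outcome
45,13,FN,population tractography outcome
45,14,TN,population tractography outcome
45,24,FN,population tractography outcome
45,25,TN,population tractography outcome
45,32,FP,population tractography outcome
47,10,RTP,population tractography outcome
47,11,TP,reconciled with printed partition tallies
47,13,RTP,population tractography outcome
47,14,RTP,population tractography outcome
47,24,FN,population tractography outcome
47,25,TN,population tractography outcome
47,32,FP,population tractography outcome
10,11,RTP,population tractography outcome
10,13,RTP,population tractography outcome
10,14,RTP,population tractography outcome
10,24,TP,conflicting subsection labels; orbital/cingulate subsection adopted
10,25,RTP,population tractography outcome
10,32,RTP,population tractography outcome
11,13,RTP,population tractography outcome
11,14,RTP,population tractography outcome
11,24,FN,population tractography outcome
11,25,TN,population tractography outcome
11,32,FP,population tractography outcome
13,14,RTP,population tractography outcome
13,24,FN,population tractography outcome
13,25,FN,population tractography outcome
13,32,TN,reconciled with printed partition tallies
14,24,TP,population tractography outcome
14,25,RTP,population tractography outcome
14,32,RTP,population tractography outcome
24,25,RTP,population tractography outcome
24,32,RTP,population tractography outcome
25,32,RTP,population tractography outcome
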