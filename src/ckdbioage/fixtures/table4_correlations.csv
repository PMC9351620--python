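# Pairwise Pearson correlations between chronological age and candidate
# biomarkers in the 133-patient CKD training cohort (published values;
# symmetric matrix completed from the printed upper triangle).
biomarker,age,ctca,creatinine,weight,height,bmi,egfr,sbp,dbp,ckd_stage,gender
age,1.0,0.249,-0.202,-0.234,-0.138,-0.173,-0.233,-0.151,-0.411,0.122,0.017
ctca,0.249,1.0,0.021,0.045,0.106,0.007,-0.056,0.009,-0.134,0.062,0.226
creatinine,-0.202,0.021,1.0,0.042,0.113,-0.018,-0.641,0.179,0.021,0.716,0.066
weight,-0.234,0.045,0.042,1.0,0.515,0.787,0.544,0.012,0.095,-0.452,0.369
height,-0.138,0.106,0.113,0.515,1.0,-0.108,0.292,0.087,0.115,-0.287,0.713
bmi,-0.173,0.007,-0.018,0.787,-0.108,1.0,0.399,-0.045,0.023,-0.306,-0.081
egfr,-0.233,-0.056,-0.641,0.544,0.292,0.399,1.0,-0.083,0.203,-0.862,0.276
sbp,-0.151,0.009,0.179,0.012,0.087,-0.045,-0.083,1.0,0.542,0.121,-0.016
dbp,-0.411,-0.134,0.021,0.095,0.115,0.023,0.203,0.542,1.0,-0.138,0.053
ckd_stage,0.122,0.062,0.716,-0.452,-0.287,-0.306,-0.862,0.121,-0.138,1.0,-0.259
gender,0.017,0.226,0.066,0.369,0.713,-0.081,0.276,-0.016,0.053,-0.259,1.0
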