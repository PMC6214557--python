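country,total_visits,total_unique_patients,unique_chronic_patients,unique_acute_patients,meds_per_patient_mean,meds_ci_low,meds_ci_high,ctx_per_visit_mean,ctx_ci_low,ctx_ci_high,destruction_rate
El Salvador,1395,378,139,297,2.18,2.09,2.27,2.47,2.38,2.56,0.16
Ghana,409,300,89,225,3.12,2.96,3.28,3.26,3.08,3.45,0.02
India,647,284,34,268,3.61,3.49,3.73,1.30,1.22,1.39,0.04
Nicaragua,1236,405,126,378,3.06,2.97,3.15,3.41,3.29,3.54,0.05
Peru,402,200,122,162,2.05,1.92,2.18,2.05,1.91,2.18,0.10
Philippines,2213,373,171,241,2.58,2.54,2.62,1.25,1.21,1.29,0.06
Romania,1566,315,141,193,2.84,2.75,2.93,3.62,3.31,3.92,0.03
Tanzania,261,96,15,89,2.49,2.21,2.77,2.79,2.47,3.18,0.02
U.S.,2102,638,348,419,2.37,2.26,2.48,3.61,3.39,3.32,0.24
West Bank,218,216,15,199,2.77,2.45,3.09,2.80,2.48,3.12,0.02
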