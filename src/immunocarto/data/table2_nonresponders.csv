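patient_id,age,sex,diagnosis,treatment,Th1,Th2,Th17,module_matching,rematched_treatment_response
NR_001,67,M,AD,Dupilumab,0.82,0.11,0.32,non matched,
NR_002,66,M,AD,Dupilumab,0.61,0.5,0.25,non matched,
NR_003,66,M,AD,Dupilumab,0.66,0.29,0.52,non matched,
NR_004,79,M,AD,Dupilumab,0.6,0.42,0.19,non matched,Baricitinib - 100% response
NR_005,33,M,AD,Dupilumab,0.43,0.15,0.03,non matched,Upadacitinib - 90% response
NR_006,88,F,PsO,Tildrakizumab,0.41,0.95,0.23,non matched,Dupilumab - 90% response
NR_007,65,M,PsO,Tildrakizumab,0.36,0.88,0.38,non matched,Dupilumab - 100% response
NR_008,66,M,PsO,Ixekizumab,0.05,0.84,0.33,non matched,Dupilumab - 90% response
NR_009,61,M,AD,Dupilumab,0.51,0.58,0.37,matched,
NR_010,59,M,AD,Tralokinumab,0.25,0.76,0.13,matched,
NR_011,58,M,PsO,Secukinumab,0.1,0.98,0.1,non matched,
NR_012,56,M,PsO,Secukinumab,0.32,0.96,0.12,non matched,
NR_013,65,M,PsO,Ixekizumab,0.19,0.97,0.47,non matched,
NR_014,47,F,AD,Dupilumab,0.17,0.1,0.38,non matched,
NR_015,55,M,AD,Dupilumab,0.19,0.3,0.55,non matched,
NR_016,59,M,AD,Dupilumab,0.1,0.11,0.36,non matched,
NR_017,18,F,PsO,Guselkumab,0.04,0.08,0.72,matched,
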