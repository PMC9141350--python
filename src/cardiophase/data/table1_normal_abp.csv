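person_id,group,phase,slope,spearman_rho
BACCHR,normal_abp,load,-1.6963,-0.8035
BARHEL,normal_abp,load,-0.65793,-0.9058
BROSOR,normal_abp,load,-1.6554,-0.9333
ENGBER,normal_abp,load,-1.0524,-0.8161
PETTHO,normal_abp,load,-1.0029,-0.8903
STEMAR,normal_abp,load,-0.097479,-0.2168
HEIRAL,normal_abp,load,-1.6539,-0.8908
FLOPET,normal_abp,load,-1.1824,-0.8389
SCHMAR,normal_abp,load,-0.88493,-0.9515
BACCHR,normal_abp,recovery,-0.32249,-0.8024
BARHEL,normal_abp,recovery,-0.012758,-0.0486
BROSOR,normal_abp,recovery,-0.30205,-0.4667
ENGBER,normal_abp,recovery,-0.19906,-0.8389
PETTHO,normal_abp,recovery,-0.90867,-0.9244
STEMAR,normal_abp,recovery,-0.25354,-0.8146
HEIRAL,normal_abp,recovery,-0.94723,-0.7538
FLOPET,normal_abp,recovery,-0.35497,-0.8024
SCHMAR,normal_abp,recovery,-0.16869,-0.8066
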