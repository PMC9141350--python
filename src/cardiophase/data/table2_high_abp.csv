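person_id,group,phase,slope,spearman_rho
ADAWOL,high_abp,load,-2.3278,-0.6960
BRODOR,high_abp,load,-2.229,-0.7972
ILLBJO,high_abp,load,-2.1799,-0.4745
NAUTHO,high_abp,load,-1.4895,-0.9701
STETHO,high_abp,load,-1.6843,-0.9066
PFEAND,high_abp,load,-2.3957,-0.8654
NEUCHR,high_abp,load,-0.48277,-0.6097
LINUWE,high_abp,load,-0.97304,-0.4954
KRAHAR,high_abp,load,-0.80256,-0.8742
KLITOR,high_abp,load,-2.071,-0.9449
ADAWOL,high_abp,recovery,-0.61569,-0.9119
BRODOR,high_abp,recovery,-0.66062,-0.9624
ILLBJO,high_abp,recovery,-0.43314,-0.6869
NAUTHO,high_abp,recovery,-0.48034,-0.9157
STETHO,high_abp,recovery,-0.748,-0.9758
PFEAND,high_abp,recovery,-0.152,-0.7833
NEUCHR,high_abp,recovery,-0.13909,-0.8257
LINUWE,high_abp,recovery,-0.14123,-0.7500
KRAHAR,high_abp,recovery,-0.38448,-0.8074
KLITOR,high_abp,recovery,-0.63648,-0.9222
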