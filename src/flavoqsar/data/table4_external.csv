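compound,inhibitory_efficiency_pct,observed_class,calculated_pfar,predicted_class
Naringenin,56.93,active_inhibitor,-0.39,active_inhibitor
Quercetin,72.73,active_inhibitor,-0.04,active_inhibitor
Morin,56.63,active_inhibitor,-0.07,active_inhibitor
Silymarin,60,active_inhibitor,0.42,inducer
Epigallocatechin gallate (EGCG),168.18,strong_inhibitor,-1.03,strong_inhibitor
Epicatechin gallate (ECG),95.45,active_inhibitor,-0.61,active_inhibitor
Biochenin A,198.04,strong_inhibitor,-1.30,strong_inhibitor
Hesperidin,164.41,strong_inhibitor,-1.32,strong_inhibitor
Demethylnobiletin,87.43,active_inhibitor,-1.13,strong_inhibitor
5HHMF,65.47,active_inhibitor,0.44,inducer
Nobiletin,45.71,active_inhibitor,1.58,inducer
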