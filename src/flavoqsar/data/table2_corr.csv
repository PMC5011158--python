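descriptor,RDF_PiChg_86,RDF_SigChg_76,3DACorr_TotChg_9,RDF_LpEN_54,3DACorr_PiChg_9,RDF_SigChg_57
RDF_PiChg_86,1.0,0.288,0.572,0.529,-0.745,0.444
RDF_SigChg_76,0.288,1.0,0.377,-0.035,-0.315,0.629
3DACorr_TotChg_9,0.572,0.377,1.0,0.448,-0.299,0.287
RDF_LpEN_54,0.529,-0.035,0.448,1.0,-0.290,-0.033
3DACorr_PiChg_9,-0.745,-0.315,-0.299,-0.290,1.0,-0.477
RDF_SigChg_57,0.444,0.629,0.287,-0.033,-0.477,1.0
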