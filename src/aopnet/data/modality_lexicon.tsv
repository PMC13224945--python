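keyword	modality
patch clamp	in vitro
cell culture	in vitro
cardiomyocyte	in vitro
organoid	in vitro
hipsc	in vitro
microelectrode array	in vitro
luciferase	in vitro
elisa	in vitro
western blot	in vitro
immunostaining	in vitro
fluorescent probe	in vitro
biochemical assay	in vitro
reporter assay	in vitro
seahorse	in vitro
flow cytometry	in vitro
echocardiograph	in vivo
electrocardiogram	in vivo
ecg	in vivo
telemetry	in vivo
histopathology	in vivo
rodent	in vivo
zebrafish	in vivo
blood pressure	in vivo
cohort	in vivo
serum	in vivo
necropsy	in vivo
simulation	in silico
computational model	in silico
in silico	in silico
qsar	in silico
docking	in silico
action potential model	in silico
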