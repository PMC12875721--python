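code,name,group
AbSen,Antibiotic sensitivity,physiology
Absor,Absorbance,physiology
FlgSn,Flagella staining,physiology
GrStn,Gram staining,physiology
CMspy,Confocal microscopy,microscopy
eMspy,Electron microscopy,microscopy
EMspy,Epifluorescence microscopy,microscopy
LMspy,Light microscopy,microscopy
PMspy,Phase contrast microscopy,microscopy
Plate,Agar plate counting,counting
Flow,Flow cytometry,counting
Sequ,16S/18S sequencing,sequencing
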