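code,name,category
CoCu,Bacterial co-culturing,Biological
SePd,Selective predation,Biological
PhoX,Phototaxis,Biological
AntB,Antibiotics,Chemical
LysZ,Lysozyme,Chemical
Chlo,Hypochlorite,Chemical
Dtrg,Surfactants,Chemical
Phen,Phenol,Chemical
Anox,Anoxy,Chemical
PhoS,Dye-based photosensitisation,Chemical
Salt,Salt solution,Chemical
Ctfg,Centrifugation,Physical
StPl,Streak plating,Physical
Wash,Washing,Physical
Mkpk,Micropicking,Physical
Fltr,Filtration,Physical
DenG,Density gradient,Physical
UltS,Ultrasonication,Physical
SubC,Subculturing,Physical
Mifl,Microfluidics,Physical
FrPr,French press,Physical
SrDl,Serial dilution,Physical
Resn,Adsorptive resin,Physical
FlCy,Flow cytometry,Physical
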