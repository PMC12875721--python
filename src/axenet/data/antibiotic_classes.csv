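compound,class
streptomycin,Aminoglycosides
kanamycin,Aminoglycosides
neomycin,Aminoglycosides
gentamicin,Aminoglycosides
amikacin,Aminoglycosides
imipenem,Carbapenems
meropenem,Carbapenems
ciprofloxacin,Fluoroquinolones
levofloxacin,Fluoroquinolones
norfloxacin,Fluoroquinolones
nalidixic acid,Fluoroquinolones
penicillin-g,Penicillins
ampicillin,Penicillins
carbenicillin,Penicillins
piperacillin,Penicillins
amoxicillin,Penicillins
tetracycline,Tetracyclines
doxycycline,Tetracyclines
chlortetracycline,Tetracyclines
oxytetracycline,Tetracyclines
cefotaxime,Cephalosporins
ceftazidime,Cephalosporins
cephalexin,Cephalosporins
cefepime,Cephalosporins
erythromycin,Macrolides
azithromycin,Macrolides
clarithromycin,Macrolides
polymyxin-b,Polypeptides
bacitracin,Polypeptides
colistin,Polypeptides
rifampicin,Rifamycins
rifamycin,Rifamycins
nitrofurantoin,Nitrofurans
furazolidone,Nitrofurans
nystatin,Antifungal Agents
amphotericin-b,Antifungal Agents
cycloheximide,Antifungal Agents
ketoconazole,Antifungal Agents
griseofulvin,Antifungal Agents
chloramphenicol,Others
sulfamethoxazole,Others
trimethoprim,Others
vancomycin,Others
gramicidin,Others
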