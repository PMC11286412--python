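drug,category
lisinopril,cardiovascular drugs
enalapril,cardiovascular drugs
perindopril,cardiovascular drugs
ramipril,cardiovascular drugs
losartan,cardiovascular drugs
valsartan,cardiovascular drugs
amlodipine,cardiovascular drugs
hydrochlorothiazide and lisinopril,cardiovascular drugs
alteplase,antithrombotic agents
carbasalate calcium,antithrombotic agents
ibuprofen,anti-inflammatory analgesics
naproxen,anti-inflammatory analgesics
diclofenac,anti-inflammatory analgesics
celecoxib,anti-inflammatory analgesics
paracetamol,anti-inflammatory analgesics
pregabalin,anti-inflammatory analgesics
amoxicillin,antibiotics
amoxicillin potassium clavulanate combination,antibiotics
clarithromycin,antibiotics
lansoprazole,digestive system drugs
omeprazole,digestive system drugs
infliximab,immunosuppressors
adalimumab,immunosuppressors
etanercept,immunosuppressors
secukinumab,immunosuppressors
sitagliptin phosphate,blood sugar control drugs
cetirizine,antiallergic drugs
omalizumab,antiasthmatics
montelukast,antiasthmatics
lenalidomide,antitumor drugs
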