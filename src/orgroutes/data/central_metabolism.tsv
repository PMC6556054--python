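Metabolite ID	Common name
FRUCTOSE-6P	beta-D-fructofuranose 6-phosphate
2-KETOGLUTARATE	2-oxoglutarate
G3P	3-phospho-D-glycerate
ERYTHROSE-4P	D-erythrose 4-phosphate
D-glucopyranose-6-phosphate	D-glucopyranose 6-phosphate
GAP	D-glyceraldehyde 3-phosphate
CPD-15317	D-ribofuranose 5-phosphate
D-SEDOHEPTULOSE-7-P	D-sedoheptulose 7-phosphate
ACETYL-COA	acetyl-CoA
OXALACETIC_ACID	oxaloacetate
PHOSPHO-ENOL-PYRUVATE	phosphoenolpyruvate
PYRUVATE	pyruvate
SUC-COA	succinyl-CoA
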