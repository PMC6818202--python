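generic	synonym
AMOXICILLIN	AMOXIL
AMOXICILLIN	AMOXICILLIN TRIHYDRATE
AZITHROMYCIN	ZITHROMAX
AZITHROMYCIN	ZMAX
AZITHROMYCIN	AZITHROMYCIN DIHYDRATE
CEFACLOR	CECLOR
CEFDINIR	OMNICEF
CEFDITOREN	SPECTRACEF
CEFDITOREN	CEFDITOREN PIVOXIL
CEFTRIAXONE	ROCEPHIN
CIPROFLOXACIN	CIPRO
CIPROFLOXACIN	CIPROFLOXACIN HYDROCHLORIDE
CLARITHROMYCIN	BIAXIN
DAPTOMYCIN	CUBICIN
ERYTHROMYCIN	ERY-TAB
ERYTHROMYCIN	ERYTHROCIN
LEVOFLOXACIN	LEVAQUIN
LINEZOLID	ZYVOX
MEROPENEM	MERREM
MEROPENEM	MEROPENEM TRIHYDRATE
NORFLOXACIN	NOROXIN
PIPERACILLIN-TAZOBACTAM	ZOSYN
PIPERACILLIN-TAZOBACTAM	PIPERACILLIN/TAZOBACTAM
PIPERACILLIN-TAZOBACTAM	PIPERACILLIN SODIUM/TAZOBACTAM SODIUM
TRIMETHOPRIM-SULFAMETHOXAZOLE	BACTRIM
TRIMETHOPRIM-SULFAMETHOXAZOLE	SEPTRA
TRIMETHOPRIM-SULFAMETHOXAZOLE	SULFAMETHOXAZOLE/TRIMETHOPRIM
VANCOMYCIN	VANCOCIN
ATORVASTATIN	LIPITOR
ATORVASTATIN	ATORVASTATIN CALCIUM
FLUVASTATIN	LESCOL
LOVASTATIN	MEVACOR
LOVASTATIN	ALTOPREV
PITAVASTATIN	LIVALO
PRAVASTATIN	PRAVACHOL
PRAVASTATIN	PRAVASTATIN SODIUM
ROSUVASTATIN	CRESTOR
ROSUVASTATIN	ROSUVASTATIN CALCIUM
SIMVASTATIN	ZOCOR
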