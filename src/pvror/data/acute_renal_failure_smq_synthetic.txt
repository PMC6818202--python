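# SYNTHETIC stand-in term list for an acute-renal-failure SMQ.
# MedDRA SMQ content is licensed and cannot be redistributed; this small
# PT list exists so tests and examples can exercise condition flagging.
# Supply a real SMQ export for production use.  The pipeline always adds
# the literal PT "Renal failure acute" to the AKI definition regardless.
Acute kidney injury
Renal failure acute
Renal failure
Anuria
Oliguria
Renal impairment
Blood creatinine increased
Glomerular filtration rate decreased
Nephropathy toxic
Azotaemia
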