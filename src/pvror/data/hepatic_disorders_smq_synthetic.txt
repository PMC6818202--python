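# SYNTHETIC stand-in term list for a hepatic-disorders SMQ.
# MedDRA SMQ content is licensed and cannot be redistributed; this small
# PT list exists so tests and examples can exercise condition flagging.
# Supply a real SMQ export for production use.
Hepatic failure
Hepatitis acute
Hepatitis fulminant
Liver injury
Hepatotoxicity
Hepatomegaly
Jaundice
Hepatic enzyme increased
Alanine aminotransferase increased
Aspartate aminotransferase increased
Blood bilirubin increased
Hepatic cirrhosis
Hepatic steatosis
Hepatorenal syndrome
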