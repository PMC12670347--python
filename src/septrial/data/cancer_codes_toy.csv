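code,category
C18,solid
C34,solid
C50,solid
C61,solid
C82,hematological
C83,hematological
C90,hematological
C91,hematological
C77,metastasized
C78,metastasized
C79,metastasized
C80,metastasized
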