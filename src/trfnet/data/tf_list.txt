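Mybl1
Fos
Giot1
Arid4b
Zfp347
Gabpa
Nr4a1
Pbrm1
Lin28a
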