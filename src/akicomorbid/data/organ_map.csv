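range_start,range_end,organ
I05,I09,heart
I16,I52,heart
I60,I69,brain
G00,G99,brain
J00,J99,lung
K70,K77,liver
K20,K63,gut
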