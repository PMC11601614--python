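name	chromosome	start	stop	assembly
PRKN	chr6	161347557	162727802	hg38
LINGO2	chr9	27948085	29213000	hg38
MAPT	chr17	45894381	46028333	hg38
SNCA	chr4	89724098	89838296	hg38
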