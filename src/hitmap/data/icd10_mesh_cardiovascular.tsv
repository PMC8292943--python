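# disease	icd10	matched (";"-joined)	excluded (";"-joined or N/A)
Hypertensive heart disease	I10-I15	C14.907.489	C13.703.395;C14.907.489.480
Ischemic heart disease	I20-I25	C14.280.647;C14.907.585	N/A
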