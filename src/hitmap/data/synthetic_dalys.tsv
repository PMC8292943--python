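# Synthetic disease-burden fixture (DALYs in thousands); values are invented
# stand-ins for demonstration and testing, not WHO estimates.
Hypertensive heart disease	6200
Ischemic heart disease	29400
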