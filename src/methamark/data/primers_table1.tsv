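name	sequence	orientation	gene	expected_product_bp
LMCRB	TWYCARGGHYTVAAYGC	forward	mcrB	392
RMCRB	CCDCCDCCDCCRTARAT	reverse	mcrB	392
LMCRG1	CAYCCDCCDYTNGADGARATGGA	forward	mcrG	356
RMCRG1	TCRAACATYANWCCRTYYTCRTC	reverse	mcrG	356
LMTAB	CARGCHAAYACYGCMATGTT	forward	mtaB	436
RMTAB	CYTGDGGRTCYCKGTA	reverse	mtaB	436
LMTBA	TTCTCCCTTGCMCAGCA	forward	mtbA	413
RMTBA	ACWGGRTCVAGRTTWCC	reverse	mtbA	413
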