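id	sequence	label
kalata_B1	GLPVCGETCVGGTCNTPGCTCSWPVCTRN	archetypal_moebius
cycloviolacin_O2	GIPCGESCVWIPCISSAIGCSCKSKVCYRN	archetypal_bracelet
syn_YS1	GLPVCGETCIGGTCNTAGCTCSWPVCTRN	archetypal_moebius
syn_YS2	GLPVCGDTCLGGTCNTVGCTCSWPVCTRN	hybrid
syn_YY1	GLPVCGETCIGGTCNTAGCTCSWPVCTR	linear
syn_HS1	GIPCGESCVWIPCITSAIGCSCKSKLCYRN	archetypal_bracelet
syn_NS1	GIPCGESCVWIPCITSAIGCSCKSKLCYRN	archetypal_bracelet
syn_PN1	GIPCGESCVWIPCITSAIGCSCKSKLCYR	linear
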