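# Synthetic stand-in node table for the flavonoid-accumulation (FLAV)
# action spectrum: a monotone decline from the UV-B into the UV-A with
# the qualitative shape reported for UV-driven flavonoid induction.
# Values are relative weights before normalisation at 300 nm.
wavelength_nm,weight
280,3.50
285,2.60
290,1.95
295,1.40
300,1.00
305,0.74
310,0.55
315,0.42
320,0.32
325,0.245
330,0.19
335,0.150
340,0.118
345,0.094
350,0.075
355,0.061
360,0.050
365,0.040
370,0.032
375,0.026
380,0.020
385,0.016
390,0.013
395,0.010
400,0.008
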