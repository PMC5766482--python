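id	start	end	region
Ig_manual_01	2704	2794	I-band
Ig_manual_02	3145	3233	I-band
Ig_manual_03	9581	9670	I-band
Ig_manual_04	12041	12133	I-band
Ig_manual_05	12321	12411	I-band
I91	12674	12765	I-band
Ig_manual_07	12854	12943	I-band
Ig_manual_08	13030	13119	I-band
Ig_manual_09	13837	13926	I-band
Ig_manual_10	14319	14411	I-band
Ig_manual_11	20618	20710	A-band
Ig_manual_12	31553	31646	A-band
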