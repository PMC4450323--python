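label	chrom	start	end
11q	11	53700000	135006516
12	12	0	133851895
13q	13	17900000	115169878
17p	17	0	24000000
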