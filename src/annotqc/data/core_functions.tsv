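# Core-function catalog (default, normative seed).
# Functions whose absence from a complete prokaryotic genome annotation is a
# red flag: each was historically found missing and added back to curated
# reference genomes (additions = number of such additions; expected_len_aa
# +/- len_sd from the curated protein clusters for the function).
# Patterns are case-insensitive substring matches, '|'-separated.
function_id	display_name	patterns	additions	expected_len_aa	len_sd
rps8	30S ribosomal protein S8	30S ribosomal protein S8|ribosomal protein S8	1	131.4	2.1
rps11	30S ribosomal protein S11	30S ribosomal protein S11|ribosomal protein S11	1	130.1	5.8
rps14	30S ribosomal protein S14	30S ribosomal protein S14|ribosomal protein S14	10	84.1	19.3
rps15	30S ribosomal protein S15	30S ribosomal protein S15|ribosomal protein S15	3	94.1	17.1
rps19	30S ribosomal protein S19	30S ribosomal protein S19|ribosomal protein S19	9	96.1	15.0
rpl2	50S ribosomal protein L2	50S ribosomal protein L2|ribosomal protein L2	1	273.8	10.2
rpl11	50S ribosomal protein L11	50S ribosomal protein L11|ribosomal protein L11	1	144.4	7.0
rpl23	50S ribosomal protein L23	50S ribosomal protein L23|ribosomal protein L23	2	99.2	10.3
rpl29	50S ribosomal protein L29	50S ribosomal protein L29|ribosomal protein L29	7	68.2	9.8
efp	elongation factor P	elongation factor P	1	185.4	16.9
fen	flap-1 endonuclease	flap-1 endonuclease|flap endonuclease	2	832.6	204.1
infA	translation initiation factor IF-1	translation initiation factor IF-1|initiation factor IF-1	4	77.3	11.1
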