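sequence	IC1	IC2	annotation
TGAGGTAGTAGATTGTATAGTT	667868	1076532	hsa-let-7f
TGAGGTAGTAGTTTGTACAGTT	363558	425364	hsa-let-7g
ACAGTAGTCTGCACATTGGTTA	342886	406433	hsa-miR-199a-3p
TAGCACCATCTGAAATCGGTTA	169479	179887	hsa-miR-29a
TGAGGTAGTAGGTTGTATAGTT	164108	256612	hsa-let-7a
TGAGGTAGTAGTTTGTGCTGTT	133623	162041	hsa-let-7i
TAGCTTATCAGACTGATGTTGA	114380	145189	hsa-miR-21
TCAGTGCATGACAGAACTTGG	49588	51885	hsa-miR-152
TGAGATGAAGCACTGTAGCTC	48131	49042	hsa-miR-143
AGCTACATTGTCTGCTGGGTTTC	46368	67564	hsa-miR-221
AGCAGCATTGTACAGGGCTATGA	39313	52911	hsa-miR-103
AACCCGTAGATCCGAACTTGTG	23084	28369	hsa-miR-100
TGAGGTAGTAGGTTGTATGGTT	21523	26641	hsa-let-7c
TGAGGTAGGAGGTTGTATAGTT	19314	29311	hsa-let-7e
TGGCTCAGTTCAGCAGGAACAG	13189	15299	hsa-miR-24
TCCCTGAGACCCTAACTTGTGA	10037	13269	hsa-miR-125b
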