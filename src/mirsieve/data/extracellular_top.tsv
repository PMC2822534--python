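sequence	EC1	EC2	EC3	annotation
TGAGGTAGTAGATTGTATAGTT	826	3653	3734	hsa-let-7f
TGAGGTAGTAGTTTGTACAGTT	679	2748	1870	hsa-let-7g
AAGCTGCCAGTTGAAGAACTGT	287	69	331	hsa-miR-22
TGGAATGTAAAGAAGTATGTAT	254	992	249	hsa-miR-1
ACAGTAGTCTGCACATTGGTTA	243	605	997	hsa-miR-199a-3p
TGAGGTAGTAGGTTGTATAGTT	215	1225	931	hsa-let-7a
TAGCTTATCAGACTGATGTTGA	182	227	644	hsa-miR-21
TCAGTGCATGACAGAACTTGG	170	100	515	hsa-miR-152
TAGCACCATCTGAAATCGGTTA	164	389	834	hsa-miR-29a
TCCCTGAGACCCTAACTTGTGA	112	42	160	hsa-miR-125b
TGAGGTAGTAGGTTGTATGGTT	95	1051	149	hsa-let-7c
TGGCTCAGTTCAGCAGGAACAG	94	40	156	hsa-miR-24
AAAAGCTGGGTTGAGAGGGCGA	87	159	100	hsa-miR-320a
TGAGGTAGTAGTTTGTGCTGTT	82	308	334	hsa-let-7i
TGAGGGGCAGAGAGCGAGACTTT	81	97	43	hsa-miR-423-5p
TGGAGAGAAAGGCAGTTCCTGA	71	55	310	hsa-miR-185
AACCCGTAGATCCGAACTTGTG	66	46	256	hsa-miR-100
TGAGATGAAGCACTGTAGCTC	66	502	277	hsa-miR-143
AGAGGTAGTAGGTTGCATAGTT	39	104	87	hsa-let-7d
AGCTACATTGTCTGCTGGGTTTC	39	111	194	hsa-miR-221
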