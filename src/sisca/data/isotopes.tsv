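# IUPAC 2013/CIAAW isotope masses (u) and representative natural abundances.
# neutron_offset is the nominal mass shift relative to the lightest isotope.
# element	isotope	mass	abundance	neutron_offset
H	1H	1.00782503207	0.999885	0
H	2H	2.01410177785	0.000115	1
C	12C	12.0	0.9893	0
C	13C	13.00335483507	0.0107	1
N	14N	14.0030740048	0.99636	0
N	15N	15.0001088989	0.00364	1
O	16O	15.9949146196	0.99757	0
O	17O	16.9991317565	0.00038	1
O	18O	17.9991596129	0.00205	2
S	32S	31.97207100	0.9499	0
S	33S	32.97145876	0.0075	1
S	34S	33.96786690	0.0425	2
S	36S	35.96708076	0.0001	4
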