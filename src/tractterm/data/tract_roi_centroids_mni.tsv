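tract	hemisphere	x	y	z
AC	L	-6	0	-7
AC	R	8	1	-7
Splenium	L	-4	-36	15
Splenium	R	4	-36	16
Cingulum	L	-12	-48	8
Cingulum	R	15	-46	8
AF	L	-33	-2	26
AF	R	32	0	23
MdLF	L	-17	-57	43
MdLF	R	21	-54	44
EmC	L	-27	10	-11
EmC	R	29	10	-10
Occ	L	-30	-72	5
Occ	R	32	-72	6
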