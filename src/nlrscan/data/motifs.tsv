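id	name	consensus	domain_class	group
1	P-loop	PIWGMGGVGKTTLARAVYNDP	NB-ARC	both
2	RNBS-D	LKPCFLYCAIFPEDYMIDKNKLIWLWMAE	NB-ARC	CNL
3	GLPL	CGGLPLAIKVWGGMLAGKQKT	NB-ARC	both
4	Kin-2	YLVVLDDVWDTDQWD	NB-ARC	both
5	RNBS-B	NGSRIIITTRNKHVANYMCT	NB-ARC	both
6	RNBS-A	HFDCRAWVCVSQQYDMKKVLRDIIQQVGG	NB-ARC	CNL
7	MHDV	CRMHDMMHDMCWYKAREQNFV	linker	both
8	linker-2	MEDVGEYYFNELINRSMFQPI	linker	both
9	LRR-LDL	LIHLRYLNLSGTNIKQLPASI	LRR	both
10	RNBS-C	LSHEESWQLFHQHAF	NB-ARC	both
11	LRR-2	MPNLETLDIHNCPNLEEIP	LRR	both
12	NB-ARC-4	IMPVLRLSYHHLPYH	NB-ARC	both
13	TIR-3	QIVIPIFYDVDPSDVRHQTGSFGEAFWKHCSR	TIR	TNL
14	monocot-1	AIKDIQEQLQKVADRRDRNKVFVPHPTRPIAIDPCLRALYAEATELVGIY	monocot	none
15	TIR-2	KNYATSRWCLNELVKIMECKE	TIR	TNL
16	EDVID	DAAYDAEDVIDSFKYHA	pre-NB	CNL
17	pre-NB-2	FAIPKLGDFLTQEYYLHKGIKKEIEWLKRELEFMQA	pre-NB	CNL
18	TIR-1	KYDVFLSFRGADTRRTFTSHLYEALKNRGINTF	TIR	TNL
19	LRR-3	IKMVEITGYRGTRFPNWMGHPVYCNMVSISIRNCKNCSCLP	LRR	both
20	monocot-2	ETSSFELMDLLGERWVPPVHLREFKSFMPSQLSALRGWIQRDPSHLSNLS	monocot	none
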