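sample	method	allele1	allele2
AT-3285	STRique	872	1056
AT-866	STRique	832	1106
GOS-3932	STRique	708	900
AT-2001	STRique	759	915
AT-1967	STRique	728	946
GOS-142	STRique	652	849
GOS-322	STRique	608	728
GOS-9443	STRique	791	824
GOS-10455	STRique	282	1062
GOS-10454	STRique	257	1055
GOS-4200	STRique	125	876
AT-3285	RP-PCR	867	1200
AT-866	RP-PCR	866	1183
GOS-3932	RP-PCR	870	1204
AT-2001	RP-PCR	704	1037
AT-1967	RP-PCR	833	1200
GOS-142	RP-PCR	654	904
GOS-322	RP-PCR	620	1054
GOS-9443	RP-PCR	870	870
GOS-10455	RP-PCR	287	1037
GOS-10454	RP-PCR	270	1004
GOS-4200	RP-PCR	120	870
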