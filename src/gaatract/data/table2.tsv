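sample	method	allele1	allele2
AT-3285	Alfred-plus	823	1007
AT-866	Alfred-plus	807	1067
GOS-3932	Alfred-plus	707	845
AT-2001	Alfred-plus	751	847
AT-1967	Alfred-plus	733	921
GOS-142	Alfred-plus	652	788
GOS-322	Alfred-plus	603	725
GOS-9443	Alfred-plus	803	842
GOS-10455	Alfred-plus	318	1071
GOS-10454	Alfred-plus	271	na
GOS-4200	Alfred-plus	123	855
HC	Alfred-plus	8	8
AT-3285	Alfred-minus	918	1127
AT-866	Alfred-minus	864	1158
GOS-3932	Alfred-minus	731	934
AT-2001	Alfred-minus	779	847
AT-1967	Alfred-minus	769	1006
GOS-142	Alfred-minus	690	880
GOS-322	Alfred-minus	654	744
GOS-9443	Alfred-minus	834	850
GOS-10455	Alfred-minus	305	1110
GOS-10454	Alfred-minus	293	1079
GOS-4200	Alfred-minus	131	918
HC	Alfred-minus	8	8
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
HC	STRique	8	8
AT-3285	Tandem-genotypes	609	950
AT-866	Tandem-genotypes	524	931
GOS-3932	Tandem-genotypes	613	862
AT-2001	Tandem-genotypes	572	829
AT-1967	Tandem-genotypes	602	901
GOS-142	Tandem-genotypes	573	822
GOS-322	Tandem-genotypes	490	709
GOS-9443	Tandem-genotypes	583	822
GOS-10455	Tandem-genotypes	304	1020
GOS-10454	Tandem-genotypes	286	976
GOS-4200	Tandem-genotypes	115	899
HC	Tandem-genotypes	1	4
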