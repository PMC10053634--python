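sample	age_at_onset
AT-3285	2
AT-866	10
GOS-3932	12
AT-2001	13
AT-1967	15
GOS-142	16
GOS-322	16
GOS-9443	18
GOS-10455	30
GOS-10454	35
GOS-4200	44
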