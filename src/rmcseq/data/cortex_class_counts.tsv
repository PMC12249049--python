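class	count
ZCG	4005
LCG	32533
EEG	12901
NRG	7430
URG	3729
DRG	2105
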