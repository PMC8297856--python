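# Illustrative example gene list for demonstration runs (not ground truth):
# genes reported higher in surgical aspirates than in matched tumour cores.
ABCB9
ACY3
CEACAM5
GAGE12F
GAGE12G
GJC2
IGHV4OR15-8
NAT8L
PHYHD1
PI16
TACR3
SLC13A5
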