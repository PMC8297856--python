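# Illustrative example gene list for demonstration runs (not ground truth):
# genes reported lower in surgical aspirates than in matched tumour cores.
ARHGAP28
CKAP2
EDARADD
HOXD8
RORC
SLC5A1
ZNF486
ZNF92
ZNF705B
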