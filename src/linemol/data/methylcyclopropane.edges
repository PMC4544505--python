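# 4-bead lumped model of methylcyclopropane
# (hydrogens absorbed onto the carbon backbone)
1 2
2 3
2 4
3 4
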