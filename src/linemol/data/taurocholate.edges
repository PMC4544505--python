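# 12-bead coarse-grained taurocholate bile salt model
# (three-to-one mapping of Vila Verde and Frenkel)
1 2
2 3
2 4
3 5
4 5
5 6
6 7
7 8
8 9
1 10
3 11
4 12
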