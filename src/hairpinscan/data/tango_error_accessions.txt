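# UniProt accessions of reviewed human-proteome entries known to make the
# external per-residue predictor fail; usable as a ready-made skip-list.
Q8NHP1
P22352
P59796
P18283
P07203
Q9C0D9
P36969
Q8IZQ5
Q9BVL4
Q9BQE4
Q8WWX9
P49908
P62341
P59797
Q9NZV5
P63302
Q9Y6D0
O60613
Q99611
Q9NNW7
Q86VQ6
Q8WZ42
P49895
Q92813
P55073
Q9NZV6
Q16881
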