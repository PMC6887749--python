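species,members
Malus domestica,191
Pyrus communis,174
Prunus persica,138
Prunus avium,118
Prunus dulcis,141
Fragaria vesca,122
Rubus occidentalis,98
Prunus mume,162
Rosa chinensis,179
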