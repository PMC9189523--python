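gene	axis
Pax3	dorsal
Pax6	dorsal
Pax7	dorsal
Msx1	dorsal
Msx2	dorsal
Ascl1	dorsal
Zic1	dorsal
Olig3	dorsal
Wnt1	dorsal
Gdf7	dorsal
Lmx1a	dorsal
Nkx6-1	ventral
Nkx2-2	ventral
Nkx2-9	ventral
Olig2	ventral
Shh	ventral
Foxa2	ventral
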