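# Synthetic placeholder spheroid dimensions per larval instar (editable).
# Length = full body length, width = head width (equatorial diameter).
# Chosen so spheroid volumes sit at the published per-instar scale
# (~0.06 mm^3 for L1 up to ~4.5 mm^3 for L4); replace with measured values.
instar,length_mm,width_mm
1,1.8,0.26
2,3.0,0.45
3,5.0,0.68
4,8.0,1.03
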