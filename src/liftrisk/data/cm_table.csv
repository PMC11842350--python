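# Coupling multiplier (CM) lookup: hand-to-object coupling quality crossed
# with the vertical location band (V < 75 cm vs V >= 75 cm).
coupling,vlt75,vge75
good,1.00,1.00
fair,0.95,1.00
poor,0.90,0.90
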