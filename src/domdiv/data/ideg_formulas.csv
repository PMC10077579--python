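formula,role
C13H12O7,neg
C14H14O7,neg
C13H12O8,neg
C14H14O8,neg
C15H16O8,neg
C13H18O7,pos
C14H20O7,pos
C15H22O7,pos
C15H22O8,pos
C16H24O8,pos
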