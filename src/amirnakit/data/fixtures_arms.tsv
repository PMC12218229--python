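# 1-based closed intervals of the mature arms on the padded pri sequences
id	arm5p_start	arm5p_end	arm3p_start	arm3p_end
pri-let-7a-1	31	52	82	102
pri-mir-26b	37	57	72	93
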