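# Nuclear-receptor annotation for TFs appearing in the screen summaries.
# The four ecdysone-related nuclear receptors among the Y1H hit set.
tf_id	is_nuclear_receptor
Hr78	1
Hr38	1
Hr46	1
Eip78C	1
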