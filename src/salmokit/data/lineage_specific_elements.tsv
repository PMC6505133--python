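# Published abundances of lineage-specific repeat elements (present in one
# genome, absent from the other).
element	grayling_bp	salmon_bp
hAT-10	123702	0
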