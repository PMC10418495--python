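region	start	end	n	at_pct	gc_pct
I	1	49	49	55.10	44.90
II	50	619	570	52.98	47.02
III	620	980	361	70.91	29.09
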