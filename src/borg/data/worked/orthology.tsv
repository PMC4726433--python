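human	1	mouse	11
human	2	mouse	12
human	1	rat	21
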