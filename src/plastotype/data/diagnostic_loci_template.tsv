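name	mechanism	enzyme_site	anchor5	anchor3	expected_deletion_len	reference_gap
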