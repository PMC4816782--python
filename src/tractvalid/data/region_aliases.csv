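alias,refers_to,note
MSTi,MSTl,"name used in the false-connection tables; relation to MSTl recorded as an alias, not resolved"
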