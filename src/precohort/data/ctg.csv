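code,description
12000,consultation
12001,home visit
12004,telephone consultation
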