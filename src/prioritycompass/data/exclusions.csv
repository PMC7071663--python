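code
3.1
3.2
3.3
3.13
3.14
3.15
3.27
3.28
3.42
4.1
4.2
4.3
4.4
4.5
4.6
4.7
4.8
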