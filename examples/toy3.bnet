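# Three-component example network:
# x1 inverts itself, x2 latches once x1 or x2 fires, x3 needs x1 without x2
targets, factors
x1, !x1
x2, x1 | x2
x3, x1 & !x2
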