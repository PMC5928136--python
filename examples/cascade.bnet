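# Damage -> inflammation relay: dmg is an input, the signal runs
# dmg -> kin -> mod -> tf; tf self-sustains unless the inhibitor inh is on;
# the cytokine il reads tf.
targets, factors
dmg, dmg
kin, dmg & !inh
mod, kin
tf, mod | (tf & !inh)
inh, 0
il, tf
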