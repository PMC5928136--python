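# Which perturbations of the relay silence the cytokine under damage?
network: cascade.bnet
fixed:
  dmg: 1
candidates: [kin, tf, inh]
max_size: 2
requirements:
  - mode: must_not_exist
    components: [il]
    pattern: [[1]]
engine: sat
workers: 1
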