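# 50-mm craniectomy over the superficial tumor, no resection
name: circle50
seed: 1
phantom:
  variant: superficial
  target_edge_length: 6.0
surgery:
  kind: circle
  diameter: 50.0
  center_direction: [1.0, 0.0, 0.0]
resection: false
pairs: [LR, AP]
current: 0.9
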