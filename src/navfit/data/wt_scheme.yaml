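states:
- IC3
- IC2
- IF
- IS
- C3
- C2
- C1
- O
conducting_states:
- O
edges:
- - IC3
  - IC2
  - a11
- - IC2
  - IC3
  - b11
- - IC2
  - IF
  - a12
- - IF
  - IC2
  - b12
- - C3
  - C2
  - a11
- - C2
  - C3
  - b11
- - C2
  - C1
  - a12
- - C1
  - C2
  - b12
- - C1
  - O
  - a13
- - O
  - C1
  - b13
- - IC3
  - C3
  - a3
- - C3
  - IC3
  - b3
- - IC2
  - C2
  - a3
- - C2
  - IC2
  - b3
- - IF
  - C1
  - a3
- - C1
  - IF
  - b3
- - O
  - IF
  - a2
- - IF
  - O
  - b2
- - O
  - IS
  - ax
- - IS
  - O
  - bx
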