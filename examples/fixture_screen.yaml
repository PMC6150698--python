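# Packaged fixture screen: 10 overlapping candidate pairs (4 strong
# excitatory, 2 inhibitory-from-elevated-baseline, 4 unconnected) and
# 20 non-overlapping control pairs, 6 flies each, 30-pulse protocol.
seed: 42
n_flies: 6
pulse_counts:
- 30
analysis_pulses: 30
bootstrap_B: 10000
pairs:
- pre: T01
  post: T02
  kind: strong_excitation
  overlapping: true
- pre: T03
  post: T04
  kind: strong_excitation
  overlapping: true
- pre: T05
  post: T06
  kind: strong_excitation
  overlapping: true
- pre: T07
  post: T08
  kind: strong_excitation
  overlapping: true
- pre: T09
  post: T10
  kind: inhibition
  overlapping: true
- pre: T11
  post: T12
  kind: inhibition
  overlapping: true
- pre: T13
  post: T14
  kind: none
  overlapping: true
- pre: T15
  post: T16
  kind: none
  overlapping: true
- pre: T17
  post: T18
  kind: none
  overlapping: true
- pre: T19
  post: T20
  kind: none
  overlapping: true
- pre: T21
  post: T22
  kind: none
  overlapping: false
- pre: T23
  post: T24
  kind: none
  overlapping: false
- pre: T25
  post: T26
  kind: none
  overlapping: false
- pre: T27
  post: T28
  kind: none
  overlapping: false
- pre: T29
  post: T30
  kind: none
  overlapping: false
- pre: T31
  post: T32
  kind: none
  overlapping: false
- pre: T33
  post: T34
  kind: none
  overlapping: false
- pre: T35
  post: T36
  kind: none
  overlapping: false
- pre: T37
  post: T38
  kind: none
  overlapping: false
- pre: T39
  post: T40
  kind: none
  overlapping: false
- pre: T41
  post: T42
  kind: none
  overlapping: false
- pre: T43
  post: T44
  kind: none
  overlapping: false
- pre: T45
  post: T46
  kind: none
  overlapping: false
- pre: T47
  post: T48
  kind: none
  overlapping: false
- pre: T49
  post: T50
  kind: none
  overlapping: false
- pre: T51
  post: T52
  kind: none
  overlapping: false
- pre: T53
  post: T54
  kind: none
  overlapping: false
- pre: T55
  post: T56
  kind: none
  overlapping: false
- pre: T57
  post: T58
  kind: none
  overlapping: false
- pre: T59
  post: T60
  kind: none
  overlapping: false
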