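# Vegetation-stage Mamdani FIS: streamside (10 m) and riparian (40 m)
# forage-index summaries -> dam capacity supported by vegetation.
# Membership breakpoints and rules are editable; defaults adapted from
# the BRAT dam-capacity framework. Rule rows: [streamside, riparian, capacity].
name: vegetation dam capacity inference
resolution: 0.01
antecedents:
- name: streamside_bfi
  universe:
  - 0
  - 5
  terms:
    unsuitable:
    - 0
    - 0
    - 0.5
    - 1
    barely:
    - 0.5
    - 1
    - 1.5
    - 2.5
    moderate:
    - 1.5
    - 2.5
    - 3
    - 3.5
    suitable:
    - 3
    - 3.5
    - 4
    - 4.5
    preferred:
    - 4
    - 4.5
    - 5
    - 5
- name: riparian_bfi
  universe:
  - 0
  - 5
  terms:
    unsuitable:
    - 0
    - 0
    - 0.5
    - 1
    barely:
    - 0.5
    - 1
    - 1.5
    - 2.5
    moderate:
    - 1.5
    - 2.5
    - 3
    - 3.5
    suitable:
    - 3
    - 3.5
    - 4
    - 4.5
    preferred:
    - 4
    - 4.5
    - 5
    - 5
consequent:
  name: capacity
  universe:
  - 0
  - 30
  terms:
    none:
    - 0
    - 0
    - 0.1
    - 0.5
    rare:
    - 0.1
    - 0.5
    - 1
    - 1.5
    occasional:
    - 1
    - 1.5
    - 4
    - 5
    frequent:
    - 4
    - 5
    - 12
    - 20
    pervasive:
    - 12
    - 20
    - 30
    - 30
rules:
- - unsuitable
  - unsuitable
  - none
- - barely
  - unsuitable
  - rare
- - moderate
  - unsuitable
  - occasional
- - suitable
  - unsuitable
  - frequent
- - preferred
  - unsuitable
  - frequent
- - unsuitable
  - barely
  - rare
- - barely
  - barely
  - occasional
- - moderate
  - barely
  - occasional
- - suitable
  - barely
  - frequent
- - preferred
  - barely
  - frequent
- - unsuitable
  - moderate
  - rare
- - barely
  - moderate
  - occasional
- - moderate
  - moderate
  - frequent
- - suitable
  - moderate
  - frequent
- - preferred
  - moderate
  - pervasive
- - unsuitable
  - suitable
  - occasional
- - barely
  - suitable
  - frequent
- - moderate
  - suitable
  - frequent
- - suitable
  - suitable
  - pervasive
- - preferred
  - suitable
  - pervasive
- - unsuitable
  - preferred
  - occasional
- - barely
  - preferred
  - frequent
- - moderate
  - preferred
  - pervasive
- - suitable
  - preferred
  - pervasive
- - preferred
  - preferred
  - pervasive
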