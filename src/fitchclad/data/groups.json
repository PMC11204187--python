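{
  "Archaboilinae": [
    "Archaboilus shurabicus",
    "Archaboilus martynovi",
    "Archaboilus musicus",
    "Archaboilus polyneurus",
    "Archaboilus ornatus sp. n.",
    "Tasgorosailus orlovskajae",
    "Pararchaboilus cretaceus",
    "Vitimoilus captiosus",
    "Vitimoilus ovatus",
    "Vitmoilus gigantus sp. n."
  ],
  "Cyrtophyllitinae sensu lato": [
    "Archaboilus shurabicus",
    "Archaboilus martynovi",
    "Archaboilus musicus",
    "Archaboilus polyneurus",
    "Archaboilus ornatus sp. n.",
    "Tasgorosailus orlovskajae",
    "Pararchaboilus cretaceus",
    "Cyrtophyllites rogeri",
    "Vitimoilus captiosus",
    "Vitimoilus ovatus",
    "Vitmoilus gigantus sp. n."
  ],
  "Vitimoilus": [
    "Vitimoilus captiosus",
    "Vitimoilus ovatus",
    "Vitmoilus gigantus sp. n."
  ],
  "Archaboilus": [
    "Archaboilus shurabicus",
    "Archaboilus martynovi",
    "Archaboilus musicus",
    "Archaboilus polyneurus",
    "Archaboilus ornatus sp. n."
  ],
  "Archaboilus excl. polyneurus": [
    "Archaboilus shurabicus",
    "Archaboilus martynovi",
    "Archaboilus musicus",
    "Archaboilus ornatus sp. n."
  ],
  "rogeri + caii": [
    "Cyrtophyllites rogeri",
    "Liassophyllum caii"
  ],
  "outgroups": [
    "Euhagla saurensis",
    "Liassophyllum caii"
  ]
}
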