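taxon,age_code,role,alias
Archaboilus kisylkiensis,J1,excluded,
Archaboilus shurabicus,J1,ingroup,
Archaboilus martynovi,J1,ingroup,
Archaboilus similis,J1,excluded,
Archaboilus musicus,J2,ingroup,
Archaboilus polyneurus,J2,ingroup,
Archaboilus ornatus sp. n.,J2,ingroup,
Cyrtophyllites rogeri,J3,ingroup,
Pararchaboilus cretaceus,K1,ingroup,
Tasgorosailus orlovskajae,J3,ingroup,
Vitimoilus captiosus,K1,ingroup,
Vitimoilus ovatus,K1,ingroup,
Vitmoilus gigantus sp. n.,K1,ingroup,Vitimoilus gigantus sp. n.
Euhagla saurensis,,outgroup,
Liassophyllum caii,,outgroup,
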