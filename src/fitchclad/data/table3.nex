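#NEXUS
BEGIN DATA;
    DIMENSIONS NTAX=13 NCHAR=24;
    FORMAT SYMBOLS="0123" MISSING=?;
    MATRIX
    'Euhagla saurensis'           000100001000000000000000
    'Liassophyllum caii'          0121100110002100000001?0
    'Archaboilus shurabicus'      101100101101001000010112
    'Archaboilus martynovi'       101100101101001000010112
    'Archaboilus musicus'         1011001011110?1000010112
    'Archaboilus polyneurus'      101100101001?01000000101
    'Archaboilus ornatus sp. n.'  101100101111?01000010112
    'Tasgorosailus orlovskajae'   1011000001211?1000100222
    'Pararchaboilus cretaceus'    103101101101001000000?0?
    'Cyrtophyllites rogeri'       ?1211101110000000?0?0???
    'Vitimoilus captiosus'        100????011???1?111?01201
    'Vitimoilus ovatus'           103020101122011111201201
    'Vitmoilus gigantus sp. n.'   ?03?20101?12??1?????????
    ;
END;
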