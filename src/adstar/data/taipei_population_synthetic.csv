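district,population
Songshan,205000
Sinyi,230000
Daan,315000
Jhongshan,217000
Jhongjheng,160000
Datong,130000
Wanhua,193000
Wunshan,263000
Nangang,110000
Neihu,244000
Shihlin,288000
Beitou,250000
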