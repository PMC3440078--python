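Beitou	Shihlin
Shihlin	Datong
Shihlin	Jhongshan
Shihlin	Neihu
Datong	Jhongshan
Datong	Jhongjheng
Datong	Wanhua
Jhongshan	Jhongjheng
Jhongshan	Daan
Jhongshan	Songshan
Jhongshan	Neihu
Songshan	Neihu
Songshan	Sinyi
Songshan	Daan
Songshan	Nangang
Neihu	Nangang
Nangang	Sinyi
Nangang	Wunshan
Sinyi	Daan
Sinyi	Wunshan
Daan	Jhongjheng
Daan	Wunshan
Jhongjheng	Wanhua
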