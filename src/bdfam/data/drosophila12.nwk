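((((((Dmel:5.4,(Dsim:2.3,Dsec:2.3)simsec:3.1)melsimsec:7.4,(Dyak:10.4,Dere:10.4)yakere:2.4)melsub:15.1,Dana:27.9)melgroup:18.1,(Dpse:3.0,Dper:3.0)obscura:43.0)melobs:7.4,Dwil:53.4)sophophora:9.6,((Dvir:32.4,Dmoj:32.4)virmoj:10.1,Dgri:42.5)drosophila_subgenus:20.5)root;
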