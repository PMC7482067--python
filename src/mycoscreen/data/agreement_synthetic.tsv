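isolate	in_vitro	in_silico
P00	positive	positive
P01	positive	positive
P02	positive	positive
P03	positive	positive
P04	positive	positive
P05	positive	positive
P06	positive	positive
P07	negative	negative
P08	negative	negative
P09	negative	negative
P10	negative	negative
P11	negative	negative
P12	negative	negative
P13	negative	negative
P14	negative	negative
P15	negative	negative
P16	negative	negative
P17	negative	negative
P18	positive	negative
P19	positive	negative
P20	negative	positive
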